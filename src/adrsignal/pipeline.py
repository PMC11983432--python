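"""End-to-end pipeline: simulate/ingest -> screen -> profile -> detect -> compare.

A single YAML config governs all stages; every run writes a manifest
recording the config hash, seed and package version, so result directories
are reproducible and attributable.  Reruns with the same config and seed
produce identical result files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import __version__, io, simulate
from .compare import SignalSet, comparison_report, intersect_signals
from .models import MeddraMap, ReportSet
from .profiles import demographic_table, serious_ae_rates, soc_profile, top_pt_table
from .screening import screen_primary_suspect
from .signals import BcpnnPrior, detect_signals, signal_frame

logger = logging.getLogger(__name__)


@dataclass(slots=True)
class PipelineConfig:
    """Validated configuration for one pipeline run."""

    output_dir: Path
    drugs: list[str]
    level: str = "pt"
    seed: int = 0
    reports_path: Optional[Path] = None
    map_path: Optional[Path] = None
    simulate: Optional[dict] = None  # kwargs for simulate.default_config
    top_n: int = 20
    min_a: int = 0
    continuity: bool = True
    consensus: str = "any"
    prior: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.output_dir = Path(self.output_dir)
        if not self.drugs:
            raise ValueError("drug list must be non-empty")
        if self.level not in ("pt", "soc"):
            raise ValueError("level must be 'pt' or 'soc'")
        if self.consensus not in ("any", "all"):
            raise ValueError("consensus must be 'any' or 'all'")
        if self.reports_path is None and self.simulate is None:
            raise ValueError("config needs either input report paths or a simulate section")
        for p in (self.reports_path, self.map_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        inp = raw.pop("input", {}) or {}
        return cls(
            output_dir=raw.pop("output_dir", "results"),
            drugs=list(raw.pop("drugs", [])),
            reports_path=Path(inp["reports"]) if "reports" in inp else None,
            map_path=Path(inp["map"]) if "map" in inp else None,
            **raw,
        )

    def canonical(self) -> str:
        d = dataclasses.asdict(self)
        d["output_dir"] = str(d["output_dir"])
        d["reports_path"] = str(d["reports_path"]) if d["reports_path"] else None
        d["map_path"] = str(d["map_path"]) if d["map_path"] else None
        return json.dumps(d, sort_keys=True)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:16]


def _load_universe(cfg: PipelineConfig, outdir: Path) -> tuple[ReportSet, MeddraMap]:
    if cfg.simulate is not None:
        gen_cfg = simulate.default_config(seed=cfg.seed, **cfg.simulate)
        rs, truth = simulate.generate(gen_cfg)
        io.write_reports(rs, outdir / "simulated_reports.csv")
        (outdir / "ground_truth.json").write_text(
            json.dumps(
                {
                    "planted": [list(p) for p in truth.planted],
                    "expected_counts": {f"{d}|{p}": v for (d, p), v in truth.expected_counts.items()},
                    "realized_counts": {f"{d}|{p}": v for (d, p), v in truth.realized_counts.items()},
                },
                indent=1,
            ),
            encoding="utf-8",
        )
        mmap = gen_cfg.meddra_map()
    else:
        rs = io.read_reports(cfg.reports_path)
        if cfg.map_path is not None:
            mmap = io.read_meddra_map(cfg.map_path)
        else:
            from .datasets import reference_meddra_map

            mmap = reference_meddra_map()
    return rs, mmap


def run_pipeline(cfg: PipelineConfig) -> int:
    """Run all stages, writing a results directory; returns an exit status.

    On any stage failure, partial outputs are retained, a FAILED marker is
    written, and the manifest still records the run.
    """
    outdir = cfg.output_dir
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config_hash": cfg.config_hash,
        "seed": cfg.seed,
        "version": __version__,
        "status": "running",
        "files": [],
    }

    def emit(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        manifest["files"].append(name)

    try:
        universe, mmap = _load_universe(cfg, outdir)
        prior = BcpnnPrior(**cfg.prior) if cfg.prior else BcpnnPrior()

        signal_sets: list[SignalSet] = []
        for drug in cfg.drugs:
            screened = screen_primary_suspect(universe, drug)
            prefix = drug.replace(" ", "_")
            for axis in ("sex", "age_group", "continent", "year"):
                table = demographic_table(screened, axis)
                emit(f"{prefix}_demographics_{axis}.csv",
                     lambda p, t=table: t.to_frame().to_csv(p, index=False))
            prof = soc_profile(screened, mmap, drug=drug)
            emit(f"{prefix}_soc_profile.csv", lambda p, t=prof: t.to_frame().to_csv(p, index=False))
            top = top_pt_table(screened, cfg.top_n, drug=drug)
            emit(f"{prefix}_top_pt.csv", lambda p, t=top: t.to_frame().to_csv(p, index=False))
            serious = serious_ae_rates(screened)
            emit(f"{prefix}_serious_ae.csv",
                 lambda p, t=serious: t.to_frame().to_csv(p, index=False))

            results = detect_signals(
                universe, drug, mmap, level=cfg.level, prior=prior,
                continuity=cfg.continuity, min_a=cfg.min_a,
            )
            frame = signal_frame(results, mmap, drug=drug, level=cfg.level)
            emit(f"{prefix}_signals.csv", lambda p, t=frame: t.to_csv(p, index=False))
            signal_sets.append(
                SignalSet.from_pairs(
                    drug,
                    [
                        (ev, mmap.soc_of(ev) or ev)
                        for ev, s in results
                        if s.is_signal(cfg.consensus)
                    ],
                )
            )

        if len(signal_sets) >= 2:
            cr = intersect_signals(signal_sets)
            report = comparison_report(cr)
            emit("comparison_shared.csv", lambda p: report.shared_table.to_csv(p, index=False))
            emit("comparison_unique.csv", lambda p: report.unique_table.to_csv(p, index=False))
            emit("comparison.txt", lambda p: p.write_text(report.text, encoding="utf-8"))

        manifest["status"] = "ok"
        return 0
    except Exception:
        logger.exception("pipeline failed")
        manifest["status"] = "failed"
        (outdir / "FAILED").write_text("pipeline failed; see run.log\n", encoding="utf-8")
        return 1
    finally:
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1), encoding="utf-8")
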