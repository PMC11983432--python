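import pytest

from adrsignal import (
    DrugRole,
    MeddraMap,
    ReportSet,
    Seriousness,
    make_report,
)


@pytest.fixture()
def toy_map() -> MeddraMap:
    return MeddraMap(
        pt_to_soc={
            "Rash": "Skin disorders",
            "Pruritus": "Skin disorders",
            "Nausea": "Gastrointestinal disorders",
            "Diarrhoea": "Gastrointestinal disorders",
            "Dizziness": "Nervous system disorders",
        },
        soc_list=("Skin disorders", "Gastrointestinal disorders", "Nervous system disorders"),
    )


@pytest.fixture()
def small_universe() -> ReportSet:
    """Four hand-built reports spanning two drugs and two PTs."""
    return ReportSet(
        reports=[
            make_report("u1", [("drugA", DrugRole.PRIMARY_SUSPECT)], ["Rash"]),
            make_report("u2", [("drugA", DrugRole.PRIMARY_SUSPECT)], ["Nausea"]),
            make_report("u3", [("drugB", DrugRole.PRIMARY_SUSPECT)], ["Rash"]),
            make_report("u4", [("drugB", DrugRole.PRIMARY_SUSPECT)], ["Nausea"]),
        ],
        source="fixture",
    )


@pytest.fixture()
def mixed_reports() -> ReportSet:
    """Five reports where drug A is primary suspect in exactly two."""
    return ReportSet(
        reports=[
            make_report(
                "r1",
                [("drugA", DrugRole.PRIMARY_SUSPECT), ("drugB", DrugRole.CONCOMITANT)],
                ["Rash", "Nausea"],
                seriousness=frozenset([Seriousness.DEATH, Seriousness.HOSPITALIZATION]),
            ),
            make_report("r2", [("drugA", DrugRole.SECONDARY_SUSPECT)], ["Rash"]),
            make_report("r3", [("drugB", DrugRole.PRIMARY_SUSPECT)], ["Dizziness"]),
            make_report(
                "r4",
                [("drugA", DrugRole.PRIMARY_SUSPECT), ("drugC", DrugRole.INTERACTING)],
                ["Diarrhoea"],
            ),
            make_report("r5", [("drugC", DrugRole.PRIMARY_SUSPECT)], ["Nausea", "Pruritus"]),
        ],
        source="fixture",
    )
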