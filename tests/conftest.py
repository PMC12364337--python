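import datetime as dt

import pytest
from hypothesis import HealthCheck, settings

from pvsignal.faers_io import DrugEntry, SafetyReport

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_report(
    primary_id="P1",
    case_id=None,
    case_version=1,
    receipt_date=dt.date(2018, 6, 1),
    drugs=(),
    reactions=(),
):
    """Terse SafetyReport factory: drugs as (name, role) or (name, role, ai) tuples."""
    entries = []
    for seq, spec in enumerate(drugs, start=1):
        name, role, *rest = spec
        entries.append(
            DrugEntry(
                report_id=primary_id,
                seq=seq,
                role_code=role,
                verbatim_name=name,
                active_ingredient=rest[0] if rest else None,
            )
        )
    return SafetyReport(
        primary_id=primary_id,
        case_id=case_id or primary_id,
        case_version=case_version,
        receipt_date=receipt_date,
        drugs=entries,
        reactions=list(reactions),
    )


@pytest.fixture
def report_factory():
    return make_report


@pytest.fixture
def quarter_writer(tmp_path):
    """Write raw $-delimited DEMO/DRUG/REAC text and return a QuarterBundle."""
    from pvsignal.faers_io import QuarterBundle

    def _write(demo, drug, reac, label="2018Q1"):
        paths = {}
        for name, text in (("DEMO", demo), ("DRUG", drug), ("REAC", reac)):
            p = tmp_path / f"{name}{label}.txt"
            p.write_text(text, encoding="latin-1")
            paths[name] = p
        return QuarterBundle(paths["DEMO"], paths["DRUG"], paths["REAC"], label)

    return _write
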