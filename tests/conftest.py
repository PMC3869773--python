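import pytest
from hypothesis import HealthCheck, settings

from polpool.tables_io import Condition, GenePeakRecord, NON_INPUT_CONDITIONS

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_record(
    gene_id="g",
    wt=1.0,
    ko=1.0,
    wt_pj=1.0,
    ko_pj=1.0,
    inp=0.1,
    flags=True,
):
    """Build a GenePeakRecord; `flags` is a bool for all samples or a dict."""
    if isinstance(flags, bool):
        flag_map = {c: flags for c in NON_INPUT_CONDITIONS}
    else:
        flag_map = {c: flags.get(c, False) for c in NON_INPUT_CONDITIONS}
    return GenePeakRecord(
        gene_id,
        {
            Condition.WT: wt,
            Condition.KO: ko,
            Condition.WT_PJ34: wt_pj,
            Condition.KO_PJ34: ko_pj,
            Condition.INPUT: inp,
        },
        flag_map,
    )


@pytest.fixture
def record_factory():
    return make_record
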