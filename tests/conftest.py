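import numpy as np
import pytest

from zebrascreen.data_model import CohortTable, EmbryoRecord


def make_record(
    embryo_id,
    ta_baseline,
    ta_final,
    *,
    replicate_id="R1",
    group="vehicle",
    site="PCS",
    baseline_dpi=1,
    final_dpi=3,
    alive_final=True,
):
    """One embryo observed at baseline and final day (dead embryos carry no
    final tumor area)."""
    rec = EmbryoRecord(
        embryo_id=str(embryo_id),
        replicate_id=replicate_id,
        group=group,
        site=site,
    )
    rec.alive_by_dpi[baseline_dpi] = True
    rec.ta_by_dpi[baseline_dpi] = float(ta_baseline)
    rec.alive_by_dpi[final_dpi] = alive_final
    if alive_final and ta_final is not None:
        rec.ta_by_dpi[final_dpi] = float(ta_final)
    return rec


def make_cohort(pairs, *, baseline_dpi=1, final_dpi=3, **kwargs):
    """Cohort from (ta_baseline, ta_final) pairs; ta_final=None means the
    embryo died before the final day."""
    records = [
        make_record(
            f"E{i:03d}",
            b,
            f,
            baseline_dpi=baseline_dpi,
            final_dpi=final_dpi,
            alive_final=f is not None,
            **kwargs,
        )
        for i, (b, f) in enumerate(pairs, start=1)
    ]
    cohort = CohortTable(records=records, baseline_dpi=baseline_dpi, final_dpi=final_dpi)
    cohort.validate()
    return cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
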