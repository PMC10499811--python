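import numpy as np
import pandas as pd
import pytest

from lewypanel.cohort import CohortDesign, EffectBlock, generate_cohort
from lewypanel.npx import NPXMatrix


def two_group_design(
    n_con=60,
    n_dlb=40,
    n_proteins=20,
    beta=0.8,
    n_effect=3,
    sd=0.5,
    **overrides,
):
    """Small CON/DLB design with the first ``n_effect`` proteins shifted."""
    blocks = []
    if n_effect:
        blocks.append(EffectBlock("dlb_unique", n_effect, beta, 0.0))
    blocks.append(EffectBlock("null", n_proteins - n_effect, 0.0, 0.0))
    kwargs = dict(
        group_sizes={"CON": n_con, "DLB": n_dlb, "AD": 0},
        age_dist={g: (65.0, 8.0) for g in ("CON", "DLB", "AD")},
        male_frac={g: 0.5 for g in ("CON", "DLB", "AD")},
        n_proteins=n_proteins,
        effect_spec=blocks,
        within_group_sd=sd,
        age_slope_frac=0.0,
        sex_shift_frac=0.0,
        lod_quantile=0.0,
        n_batches=1,
        batch_sd=0.0,
        n_bridges=0,
    )
    kwargs.update(overrides)
    return CohortDesign(**kwargs)


@pytest.fixture(scope="session")
def small_cohort():
    """60/40 two-group cohort with 3 strong markers among 20 proteins."""
    design = two_group_design()
    return generate_cohort(design, seed=7)


@pytest.fixture(scope="session")
def three_group_cohort():
    """CON/DLB/AD cohort with all effect classes, batches and bridges."""
    blocks = [
        EffectBlock("dlb_unique", 5, 1.0, 0.0),
        EffectBlock("dlb_unique", 3, -1.0, 0.0),
        EffectBlock("general_dementia", 6, 0.9, 0.9),
        EffectBlock("shared_divergent", 6, -0.9, 0.9),
        EffectBlock("ad_specific", 4, 0.0, 0.9),
        EffectBlock("null", 16, 0.0, 0.0),
    ]
    design = CohortDesign(
        group_sizes={"CON": 80, "DLB": 60, "AD": 80},
        age_dist={"CON": (58.0, 8.0), "DLB": (69.0, 8.0), "AD": (66.0, 8.0)},
        male_frac={"CON": 0.6, "DLB": 0.8, "AD": 0.6},
        n_proteins=40,
        effect_spec=blocks,
        lod_quantile=0.02,
        n_batches=2,
        batch_sd=0.3,
        n_bridges=8,
    )
    return design, generate_cohort(design, seed=11)


def toy_matrix(values, lod=None, batch=None, samples=None, assays=None):
    """Hand-built NPXMatrix from a plain array."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    samples = samples or [f"s{i}" for i in range(n)]
    assays = assays or [f"a{j}" for j in range(p)]
    lod = lod if lod is not None else np.full(p, -np.inf * 0 - 100.0)
    batch = batch if batch is not None else ["R1"] * n
    return NPXMatrix(
        values=pd.DataFrame(values, index=samples, columns=assays),
        lod=pd.Series(np.asarray(lod, dtype=float), index=assays),
        batch=pd.Series(batch, index=samples),
    )
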