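"""Synthetic NPX cohort generation with planted ground truth.

Generates three-group (CON/DLB/AD) cohorts whose statistical structure
mirrors what the downstream analysis assumes: per-protein group effects from
named effect classes, age/sex confounding, batch offsets with bridging
samples re-measured in every round, and per-assay LOD censoring levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from lewypanel.errors import DataError
from lewypanel.npx import NPXMatrix, SampleMetadata

EFFECT_CLASSES = ("dlb_unique", "general_dementia", "shared_divergent",
                  "ad_specific", "null")

GROUPS = ("CON", "DLB", "AD")


@dataclass(frozen=True)
class EffectBlock:
    """A block of proteins sharing one effect configuration.

    ``beta_dlb`` / ``beta_ad`` are the true log2 shifts of DLB and AD
    relative to CON.  ``tag`` marks special blocks (e.g. the planted panel).
    """

    klass: str
    count: int
    beta_dlb: float
    beta_ad: float
    tag: str = ""

    def __post_init__(self):
        if self.klass not in EFFECT_CLASSES:
            raise DataError(f"unknown effect class {self.klass!r}")
        if self.count < 0:
            raise DataError("effect block count must be >= 0")
        if self.klass == "null" and (self.beta_dlb != 0 or self.beta_ad != 0):
            raise DataError("null class requires zero betas")


@dataclass
class CohortDesign:
    """Full parameterization of a synthetic cohort."""

    group_sizes: dict[str, int]
    age_dist: dict[str, tuple[float, float]]
    male_frac: dict[str, float]
    n_proteins: int
    effect_spec: list[EffectBlock]
    within_group_sd: float = 0.5
    age_slope: float = 0.02          # log2 units per year, where applied
    age_slope_frac: float = 0.2      # fraction of proteins carrying the slope
    sex_shift: float = 0.1           # log2 shift for males, where applied
    sex_shift_frac: float = 0.2
    lod_quantile: float | tuple[float, float] = (0.02, 0.15)
    n_batches: int = 2
    batch_sd: float = 0.2
    n_bridges: int = 16
    mask_below_lod: bool = False     # optional missing-data mode

    def validate(self) -> None:
        if any(n < 0 for n in self.group_sizes.values()):
            raise DataError("group sizes must be non-negative")
        if sum(n > 0 for n in self.group_sizes.values()) < 2:
            raise DataError("need at least two non-empty groups")
        for g, frac in self.male_frac.items():
            if not 0 <= frac <= 1:
                raise DataError(f"male_frac[{g}] outside [0,1]")
        for g, (mu, sd) in self.age_dist.items():
            if sd <= 0 or mu <= 0:
                raise DataError(f"age distribution for {g} must be positive")
        if self.within_group_sd <= 0:
            raise DataError("within_group_sd must be positive")
        total = sum(b.count for b in self.effect_spec)
        if total != self.n_proteins:
            raise DataError(
                f"effect block counts sum to {total}, expected n_proteins="
                f"{self.n_proteins}"
            )
        q = self.lod_quantile
        lo, hi = (q, q) if np.isscalar(q) else q
        if not (0 <= lo <= hi < 1):
            raise DataError("lod_quantile must lie in [0, 1)")
        if self.n_batches < 1 or self.n_bridges < 0 or self.batch_sd < 0:
            raise DataError("invalid batch/bridge configuration")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["effect_spec"] = [asdict(b) for b in self.effect_spec]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortDesign":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["effect_spec"] = [EffectBlock(**b) for b in d["effect_spec"]]
        d["age_dist"] = {g: tuple(v) for g, v in d["age_dist"].items()}
        if isinstance(d.get("lod_quantile"), list):
            d["lod_quantile"] = tuple(d["lod_quantile"])
        return cls(**d)


@dataclass
class TruthTable:
    """Per-protein ground truth emitted alongside a generated cohort."""

    table: pd.DataFrame  # index: protein id; columns: class, beta_dlb_vs_con,
    #                       beta_ad_vs_con, age_slope, sex_shift, mu, tag

    def __post_init__(self):
        null_rows = self.table["class"] == "null"
        betas = self.table.loc[null_rows, ["beta_dlb_vs_con", "beta_ad_vs_con"]]
        if (betas.to_numpy() != 0).any():
            raise DataError("null-class proteins must have zero betas")

    @property
    def panel_markers(self) -> list[str]:
        return list(self.table.index[self.table["tag"] == "panel"])

    def to_tsv(self, path) -> None:
        self.table.reset_index(names="protein").to_csv(path, sep="\t", index=False)


def default_paper_design() -> CohortDesign:
    """Cohort design with the study's group sizes and demographics.

    Group sizes 190/109/235 (sum 534); DLB-unique / general-dementia /
    shared-divergent classes of 49/17/24 proteins among the non-null ones.
    Seven strong DLB-vs-CON markers (one at beta 0.95) are tagged "panel"
    as the planted signature for recovery experiments.
    """
    blocks = [
        EffectBlock("dlb_unique", 1, 0.95, 0.0, tag="panel"),
        EffectBlock("dlb_unique", 3, 1.10, 0.0, tag="panel"),
        EffectBlock("dlb_unique", 3, -1.10, 0.0, tag="panel"),
        EffectBlock("dlb_unique", 14, 0.35, 0.0),
        EffectBlock("dlb_unique", 28, -0.35, 0.0),
        EffectBlock("general_dementia", 6, 0.40, 0.40),
        EffectBlock("general_dementia", 11, -0.40, -0.40),
        EffectBlock("shared_divergent", 15, -0.30, 0.30),
        EffectBlock("shared_divergent", 9, 0.30, -0.30),
        EffectBlock("ad_specific", 18, 0.0, 0.45),
        EffectBlock("ad_specific", 12, 0.0, -0.45),
        EffectBlock("null", 530, 0.0, 0.0),
    ]
    design = CohortDesign(
        group_sizes={"CON": 190, "DLB": 109, "AD": 235},
        age_dist={"CON": (58.0, 8.0), "DLB": (69.0, 8.0), "AD": (66.0, 8.0)},
        male_frac={"CON": 120 / 190, "DLB": 91 / 109, "AD": 139 / 235},
        n_proteins=650,
        effect_spec=blocks,
    )
    design.validate()
    return design


def single_marker_design(
    delta: float = 0.95,
    sd: float = 0.5,
    n_a: int = 190,
    n_b: int = 109,
    group_a: str = "CON",
    group_b: str = "DLB",
) -> CohortDesign:
    """Two-group, one-protein design for calibrated-AUC experiments.

    No confounding, batching or censoring: the marker is Gaussian within
    each group with mean shift ``delta`` and common SD ``sd``.
    """
    sizes = {"CON": 0, "DLB": 0, "AD": 0}
    sizes[group_a] = n_a
    sizes[group_b] = n_b
    design = CohortDesign(
        group_sizes=sizes,
        age_dist={g: (65.0, 8.0) for g in GROUPS},
        male_frac={g: 0.5 for g in GROUPS},
        n_proteins=1,
        effect_spec=[EffectBlock("dlb_unique", 1,
                                 delta if group_b == "DLB" else 0.0,
                                 delta if group_b == "AD" else 0.0)],
        within_group_sd=sd,
        age_slope_frac=0.0,
        sex_shift_frac=0.0,
        lod_quantile=0.0,
        n_batches=1,
        batch_sd=0.0,
        n_bridges=0,
    )
    design.validate()
    return design


def generate_cohort(
    design: CohortDesign, seed: int
) -> tuple[NPXMatrix, SampleMetadata, TruthTable]:
    """Draw one cohort from ``design``.

    Per sample i and protein j:
    ``NPX_ij = mu_j + beta_j[group(i)] + a_j*(age_i - mean age)
    + s_j*1[male] + batch offset + eps``, eps ~ N(0, within_group_sd).

    Bridge subjects are drawn from the cohort and re-measured in every
    batch as extra rows named ``BRIDGE<k>__<batch>`` (same latent signal,
    fresh measurement noise); their clinical rows carry ``is_bridge=True``.
    Per-assay LODs are set at the block's ``lod_quantile`` of the marginal
    value distribution; below-LOD values are kept unless
    ``design.mask_below_lod``.
    """
    design.validate()
    rng = np.random.default_rng(seed)

    # --- samples ----------------------------------------------------------
    groups = [g for g in GROUPS if design.group_sizes.get(g, 0) > 0]
    diag = np.concatenate([[g] * design.group_sizes[g] for g in groups])
    n = len(diag)
    sample_ids = np.array([f"S{i + 1:04d}" for i in range(n)])
    age = np.concatenate(
        [rng.normal(*design.age_dist[g], size=design.group_sizes[g]) for g in groups]
    )
    age = np.clip(age, 18.0, None)
    sex = np.concatenate(
        [
            np.where(
                rng.random(design.group_sizes[g]) < design.male_frac[g], "M", "F"
            )
            for g in groups
        ]
    )

    # --- proteins ---------------------------------------------------------
    p = design.n_proteins
    protein_ids = np.array([f"P{j + 1:04d}" for j in range(p)])
    klass = np.concatenate([[b.klass] * b.count for b in design.effect_spec])
    tag = np.concatenate([[b.tag] * b.count for b in design.effect_spec])
    beta_dlb = np.concatenate([[b.beta_dlb] * b.count for b in design.effect_spec])
    beta_ad = np.concatenate([[b.beta_ad] * b.count for b in design.effect_spec])
    mu = rng.normal(3.0, 1.0, size=p)
    a_j = np.where(rng.random(p) < design.age_slope_frac, design.age_slope, 0.0)
    s_j = np.where(rng.random(p) < design.sex_shift_frac, design.sex_shift, 0.0)

    # --- batches ----------------------------------------------------------
    batch_labels = np.array([f"R{b + 1}" for b in range(design.n_batches)])
    batch_of_sample = batch_labels[rng.permutation(np.arange(n) % design.n_batches)]
    batch_offsets = np.zeros((design.n_batches, p))
    if design.n_batches > 1 and design.batch_sd > 0:
        batch_offsets[1:] = rng.normal(0.0, design.batch_sd,
                                       size=(design.n_batches - 1, p))

    group_beta = {"CON": np.zeros(p), "DLB": beta_dlb, "AD": beta_ad}
    mean_age = float(np.mean(age)) if n else 0.0
    latent = (
        mu[None, :]
        + np.vstack([group_beta[g] for g in diag])
        + a_j[None, :] * (age - mean_age)[:, None]
        + s_j[None, :] * (sex == "M")[:, None].astype(float)
    )
    batch_idx = {b: i for i, b in enumerate(batch_labels)}
    offsets = np.vstack([batch_offsets[batch_idx[b]] for b in batch_of_sample])
    noise = rng.normal(0.0, design.within_group_sd, size=(n, p))
    values = latent + offsets + noise

    # --- bridge rows ------------------------------------------------------
    bridge_rows: list[np.ndarray] = []
    bridge_ids: list[str] = []
    bridge_batches: list[str] = []
    bridge_meta_rows: list[dict] = []
    n_bridges = min(design.n_bridges, n)
    if n_bridges > 0 and design.n_batches > 1:
        # spread bridge subjects across groups deterministically
        subjects = rng.choice(n, size=n_bridges, replace=False)
        for k, si in enumerate(subjects):
            for b in batch_labels:
                row = (
                    latent[si]
                    + batch_offsets[batch_idx[b]]
                    + rng.normal(0.0, design.within_group_sd, size=p)
                )
                rid = f"BRIDGE{k + 1:02d}__{b}"
                bridge_rows.append(row)
                bridge_ids.append(rid)
                bridge_batches.append(b)
                bridge_meta_rows.append(
                    {"sample_id": rid, "diagnosis": diag[si], "age": age[si],
                     "sex": sex[si], "cohort": "SIM", "is_bridge": True}
                )

    all_values = np.vstack([values] + ([np.vstack(bridge_rows)] if bridge_rows else []))
    all_ids = np.concatenate([sample_ids, np.array(bridge_ids, dtype=object)])
    all_batches = np.concatenate([batch_of_sample, np.array(bridge_batches, dtype=object)])

    # --- LOD --------------------------------------------------------------
    q = design.lod_quantile
    if np.isscalar(q):
        qs = np.full(p, float(q))
    else:
        qs = rng.uniform(q[0], q[1], size=p)
    lod = np.array(
        [
            np.quantile(all_values[:, j], qs[j]) if qs[j] > 0
            else all_values[:, j].min() - 1.0
            for j in range(p)
        ]
    )
    if design.mask_below_lod:
        all_values = np.where(all_values <= lod[None, :], np.nan, all_values)

    values_df = pd.DataFrame(all_values, index=all_ids, columns=protein_ids)
    matrix = NPXMatrix(
        values=values_df,
        lod=pd.Series(lod, index=protein_ids),
        batch=pd.Series(all_batches, index=all_ids),
        assay_meta=pd.DataFrame(
            {"protein": protein_ids, "panel": "SIM"}, index=protein_ids
        ),
    )

    meta_df = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "diagnosis": diag,
            "age": age,
            "sex": sex,
            "cohort": "SIM",
            "is_bridge": False,
        }
    )
    if bridge_meta_rows:
        meta_df = pd.concat(
            [meta_df, pd.DataFrame(bridge_meta_rows)], ignore_index=True
        )
    metadata = SampleMetadata(meta_df.set_index("sample_id"))

    truth = TruthTable(
        pd.DataFrame(
            {
                "class": klass,
                "beta_dlb_vs_con": beta_dlb,
                "beta_ad_vs_con": beta_ad,
                "age_slope": a_j,
                "sex_shift": s_j,
                "mu": mu,
                "tag": tag,
            },
            index=pd.Index(protein_ids, name="protein"),
        )
    )
    return matrix, metadata, truth


def bridge_base_ids(m: NPXMatrix) -> list[str]:
    """Bridge base identifiers present in a generated matrix."""
    bases = {
        s.split("__")[0] for s in m.sample_ids if str(s).startswith("BRIDGE")
    }
    return sorted(bases)


def analysis_samples(m: NPXMatrix, meta: SampleMetadata) -> NPXMatrix:
    """Drop bridge re-measurement rows before statistical analysis."""
    if "is_bridge" in meta.table.columns:
        keep = [
            s for s in m.sample_ids
            if not bool(meta.table.loc[s, "is_bridge"])
        ]
    else:
        keep = [s for s in m.sample_ids if not str(s).startswith("BRIDGE")]
    return m.subset_samples(keep)
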