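"""Hypergeometric gene-set enrichment with kappa-similarity term clustering.

Terms are tested against a caller-supplied background with the upper-tail
hypergeometric p-value; passing terms (p < 0.01, overlap >= 3, enrichment
factor > 1.5 by default) are clustered by average-linkage on Cohen's kappa
between their background membership vectors, cutting where within-subtree
similarity exceeds 0.3; the most significant term represents each cluster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from lewypanel.errors import DataError, FormatError


@dataclass
class EnrichedTerm:
    term: str
    description: str
    term_size: int          # within the background
    overlap: int
    p: float
    enrichment_factor: float
    passes_filters: bool
    cluster: int = -1
    is_cluster_representative: bool = False
    genes: tuple[str, ...] = ()


def read_gmt(path) -> dict[str, tuple[str, list[str]]]:
    """GMT reader: tab-separated ``term<TAB>description<TAB>gene...`` lines."""
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"GMT line {ln}: need term, description, genes")
            term, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if term in sets:
                raise FormatError(f"GMT line {ln}: duplicate term {term!r}")
            sets[term] = (desc, genes)
    return sets


def hypergeom_enrich(
    query: set[str] | list[str],
    background: set[str] | list[str],
    gene_sets: dict[str, tuple[str, list[str]]],
    p_max: float = 0.01,
    min_count: int = 3,
    min_enrichment: float = 1.5,
) -> list[EnrichedTerm]:
    """Upper-tail hypergeometric enrichment against ``background``.

    ``p = P(X >= overlap)`` for X ~ Hypergeom(N=|background|, K=|term|,
    n=|query|); enrichment factor is overlap over its null expectation.
    Gene sets are intersected with the background before testing.
    """
    query = set(query)
    background = set(background)
    stray = query - background
    if stray:
        raise DataError(f"query genes absent from background: {sorted(stray)[:10]}")
    N = len(background)
    n = len(query)
    out = []
    for term, (desc, genes) in gene_sets.items():
        members = set(genes) & background
        K = len(members)
        if K == 0:
            continue
        overlap = len(members & query)
        p = float(stats.hypergeom.sf(overlap - 1, N, K, n))
        expected = K * n / N
        ef = overlap / expected if expected > 0 else 0.0
        out.append(
            EnrichedTerm(
                term=term, description=desc, term_size=K, overlap=overlap,
                p=p, enrichment_factor=float(ef),
                passes_filters=(p < p_max and overlap >= min_count
                                and ef > min_enrichment),
                genes=tuple(sorted(members)),
            )
        )
    out.sort(key=lambda t: t.p)
    return out


def cohen_kappa(a: np.ndarray, b: np.ndarray) -> float:
    """Chance-corrected agreement of two boolean membership vectors."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    n = len(a)
    po = float((a == b).mean())
    pa, pb = a.mean(), b.mean()
    pe = pa * pb + (1 - pa) * (1 - pb)
    if pe == 1.0:
        return 1.0 if po == 1.0 else 0.0
    return (po - pe) / (1 - pe)


def kappa_cluster(
    terms: list[EnrichedTerm],
    background: set[str] | list[str],
    threshold: float = 0.3,
) -> list[EnrichedTerm]:
    """Average-linkage clustering of passing terms on kappa similarity.

    Subtrees whose average similarity exceeds ``threshold`` form one
    cluster; within each cluster the minimum-p term becomes the
    representative.  Returns new term objects with ``cluster`` and
    ``is_cluster_representative`` set (non-passing terms keep cluster -1).
    """
    background = sorted(set(background))
    passing = [t for t in terms if t.passes_filters]
    if not passing:
        raise DataError("no terms pass the filters; nothing to cluster")
    index = {g: i for i, g in enumerate(background)}
    M = np.zeros((len(passing), len(background)), dtype=bool)
    for ti, t in enumerate(passing):
        for g in t.genes:
            M[ti, index[g]] = True

    if len(passing) == 1:
        assignments = np.array([1])
    else:
        k = len(passing)
        dist = np.zeros((k, k))
        for i in range(k):
            for j in range(i + 1, k):
                kap = cohen_kappa(M[i], M[j])
                dist[i, j] = dist[j, i] = 1.0 - kap
        Z = linkage(squareform(dist, checks=False), method="average")
        # similarity > threshold  <=>  merge distance < 1 - threshold
        assignments = fcluster(Z, t=(1.0 - threshold) - 1e-12, criterion="distance")

    out = []
    reps: dict[int, EnrichedTerm] = {}
    for t, c in zip(passing, assignments):
        if c not in reps or t.p < reps[c].p:
            reps[c] = t
    for t in terms:
        if not t.passes_filters:
            out.append(
                EnrichedTerm(**{**t.__dict__, "cluster": -1,
                                "is_cluster_representative": False})
            )
            continue
        c = int(assignments[passing.index(t)])
        out.append(
            EnrichedTerm(**{**t.__dict__, "cluster": c,
                            "is_cluster_representative": reps[c] is t})
        )
    return out


def enrichment_table(terms: list[EnrichedTerm]) -> pd.DataFrame:
    """Result table ordered by cluster then p."""
    df = pd.DataFrame([t.__dict__ for t in terms]).drop(columns=["genes"])
    return df.sort_values(["cluster", "p"]).reset_index(drop=True)
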