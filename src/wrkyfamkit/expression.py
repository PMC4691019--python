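"""RPKM normalization, fold-change calls, clustering and 2^-ΔΔCt.

Expression values are reads per kilobase of transcript per million mapped
reads (RPKM); treatment/control contrasts are log2 ratios with a
pseudocount guarding zeros; genes are called responsive at a fold-change
threshold (default 2); heatmap row ordering comes from agglomerative
hierarchical clustering; and qRT-PCR relative expression uses the
2^-ΔΔCt method against a reference gene and a control sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "FoldChangeCall",
    "DdCtResult",
    "rpkm",
    "log2_ratio_matrix",
    "fold_change_classify",
    "hierarchical_cluster",
    "delta_delta_ct",
]


@dataclass(frozen=True)
class FoldChangeCall:
    gene_id: str
    log2_ratios: tuple[float, ...]
    response: str  # up | down | unresponsive
    bidirectional: bool = False  # crossed the threshold in both directions


@dataclass
class DdCtResult:
    samples: list[str]
    delta_ct: dict[str, float]
    dd_ct: dict[str, float]
    relative_expression: dict[str, float]
    se: dict[str, float]
    control_sample: str


def rpkm(counts, gene_length_bp, library_size) -> np.ndarray | float:
    """Reads per kilobase per million mapped reads: 10⁹·c / (L·len)."""
    counts = np.asarray(counts, dtype=float)
    length = np.asarray(gene_length_bp, dtype=float)
    lib = np.asarray(library_size, dtype=float)
    if (length <= 0).any() if length.ndim else length <= 0:
        raise ValueError("gene length must be > 0")
    if (lib <= 0).any() if lib.ndim else lib <= 0:
        raise ValueError("library size must be > 0")
    out = 1e9 * counts / (lib * length)
    return float(out) if out.ndim == 0 else out


def log2_ratio_matrix(
    matrix: pd.DataFrame, control: str, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Per-gene log2((x+ε)/(y+ε)) against the control column.

    The pseudocount ε (default 1 RPKM) bounds ratios for genes that drop
    to zero in either sample; the control column itself maps to all zeros.
    """
    if control not in matrix.columns:
        raise KeyError(f"control column {control!r} not in matrix")
    x = matrix.to_numpy(dtype=float) + pseudocount
    y = (matrix[control].to_numpy(dtype=float) + pseudocount)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.log2(x / y)
    out[x == y] = 0.0  # covers 0/0 when the pseudocount is zero
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def fold_change_classify(
    log_ratios: pd.DataFrame, threshold: float = 2.0
) -> list[FoldChangeCall]:
    """Call each gene up/down/unresponsive at a fold-change threshold.

    ``up`` when any condition reaches ≥ log2(threshold), ``down`` when any
    reaches ≤ −log2(threshold).  A gene crossing both directions is
    classed up (the stronger, induction-focused reading) and flagged
    ``bidirectional`` so no information is lost.
    """
    cut = np.log2(threshold)
    calls = []
    for gene_id, row in log_ratios.iterrows():
        vals = row.to_numpy(dtype=float)
        is_up = bool(np.nanmax(vals) >= cut)
        is_down = bool(np.nanmin(vals) <= -cut)
        if is_up:
            response = "up"
        elif is_down:
            response = "down"
        else:
            response = "unresponsive"
        calls.append(
            FoldChangeCall(str(gene_id), tuple(vals), response, is_up and is_down)
        )
    return calls


def hierarchical_cluster(
    matrix: pd.DataFrame,
    metric: Literal["euclidean", "correlation"] = "correlation",
    linkage: Literal["average", "complete"] = "average",
):
    """Agglomerative clustering of genes for heatmap row ordering.

    Returns ``(Z, leaf_order, cut)`` where ``Z`` is the scipy linkage
    matrix, ``leaf_order`` the gene ids in dendrogram order, and
    ``cut(k)`` a function assigning genes to ``k`` flat clusters.  SciPy's
    linkage resolves ties by the smallest cluster index, so the output is
    deterministic for a fixed input row order.
    """
    if len(matrix) < 2:
        raise ValueError("clustering needs at least 2 genes")
    x = matrix.to_numpy(dtype=float)
    if metric == "correlation":
        sd = x.std(axis=1)
        if (sd == 0).any():
            bad = matrix.index[np.flatnonzero(sd == 0)[0]]
            raise ValueError(
                f"gene {bad!r} has constant expression; correlation distance undefined"
            )
    d = pdist(x, metric=metric)
    z = hierarchy.linkage(d, method=linkage)
    order = [matrix.index[i] for i in hierarchy.leaves_list(z)]

    def cut(k: int) -> dict[str, int]:
        labels = hierarchy.fcluster(z, t=k, criterion="maxclust")
        return {str(g): int(l) for g, l in zip(matrix.index, labels)}

    return z, order, cut


def delta_delta_ct(
    target_ct: Mapping[str, Sequence[float]],
    reference_ct: Mapping[str, Sequence[float]],
    control_sample: str,
) -> DdCtResult:
    """Relative expression by the 2^-ΔΔCt method.

    ``target_ct``/``reference_ct`` map sample → technical-replicate Ct
    values for the gene of interest and the internal reference
    (housekeeping) gene.  ΔCt = mean Ct_target − mean Ct_reference per
    sample; ΔΔCt subtracts the control sample's ΔCt; relative expression
    is 2^−ΔΔCt (exactly 1 for the control itself).  The reported standard
    error is that of ΔCt, combining both genes' replicate SEs.
    """
    samples = list(target_ct)
    if control_sample not in samples:
        raise KeyError(f"control sample {control_sample!r} missing from target Ct table")
    delta, se = {}, {}
    for s in samples:
        if s not in reference_ct:
            raise KeyError(f"reference gene Ct missing for sample {s!r}")
        t = np.asarray(list(target_ct[s]), dtype=float)
        r = np.asarray(list(reference_ct[s]), dtype=float)
        if not (np.isfinite(t).all() and np.isfinite(r).all()):
            raise ValueError(f"non-finite Ct value in sample {s!r}")
        delta[s] = float(t.mean() - r.mean())
        se_t = t.std(ddof=1) / np.sqrt(len(t)) if len(t) > 1 else 0.0
        se_r = r.std(ddof=1) / np.sqrt(len(r)) if len(r) > 1 else 0.0
        se[s] = float(np.hypot(se_t, se_r))
    dd = {s: delta[s] - delta[control_sample] for s in samples}
    rel = {s: float(2.0 ** (-dd[s])) for s in samples}
    return DdCtResult(samples, delta, dd, rel, se, control_sample)
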