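"""Pairwise Ka/Ks (Nei–Gojobori 1986) and branch-site positive-selection tests.

The branch-site machinery implements "model A": codon sites fall into four
classes — 0 (purifying, 0 < ω0 < 1 everywhere), 1 (neutral, ω1 = 1
everywhere), 2a and 2b (purifying/neutral on background branches, ω2 ≥ 1 on
the designated foreground branch).  Class proportions satisfy
p2a/p2b = p0/p1.  Episodic positive selection on the foreground lineage is
tested by a likelihood-ratio test of this model against the same model with
ω2 fixed at 1, with the statistic 2ΔlnL referred to χ²₁.

The codon substitution process is a Markov model on the 61 sense codons:
single-nucleotide exchanges at rate π_target × κ^[transition] ×
ω^[nonsynonymous], zero rate for multi-nucleotide changes, and the
generator scaled so branch lengths are expected substitutions per codon
under the site-class mixture.
"""

from __future__ import annotations

import dataclasses
import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats
from Bio.Data.CodonTable import unambiguous_dna_by_id

from .io_formats import SequenceRecord

__all__ = [
    "CODONS",
    "KaKsResult",
    "CodonModel",
    "BranchSiteFit",
    "LrtResult",
    "ng86_kaks",
    "equal_codon_frequencies",
    "f3x4_frequencies",
    "build_generator",
    "transition_matrices",
    "codon_log_likelihood",
    "fit_branch_site_A",
    "likelihood_ratio_test",
]

# ---------------------------------------------------------------------------
# Genetic code tables
# ---------------------------------------------------------------------------

_TABLE = unambiguous_dna_by_id[1]
STOP_CODONS = set(_TABLE.stop_codons)
CODONS: list[str] = sorted(
    c for c in ("".join(p) for p in itertools.product("ACGT", repeat=3)) if c not in STOP_CODONS
)
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}
AA_OF = [_TABLE.forward_table[c] for c in CODONS]
_NCOD = len(CODONS)  # 61

_PURINES = {"A", "G"}


def _is_transition(a: str, b: str) -> bool:
    return (a in _PURINES) == (b in _PURINES)


# single-difference structure between sense codons
_DIFF_COUNT = np.zeros((_NCOD, _NCOD), dtype=int)
_SINGLE_TS = np.zeros((_NCOD, _NCOD), dtype=bool)
_SINGLE_SYN = np.zeros((_NCOD, _NCOD), dtype=bool)
for _i, _ci in enumerate(CODONS):
    for _j, _cj in enumerate(CODONS):
        diffs = [k for k in range(3) if _ci[k] != _cj[k]]
        _DIFF_COUNT[_i, _j] = len(diffs)
        if len(diffs) == 1:
            k = diffs[0]
            _SINGLE_TS[_i, _j] = _is_transition(_ci[k], _cj[k])
            _SINGLE_SYN[_i, _j] = AA_OF[_i] == AA_OF[_j]
_SINGLE = _DIFF_COUNT == 1


# ---------------------------------------------------------------------------
# NG86 pairwise Ka/Ks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KaKsResult:
    ka: float
    ks: float
    omega: float
    S: float
    N: float
    Sd: float
    Nd: float
    saturated: bool = False


def _codon_syn_sites(codon: str) -> float:
    """Synonymous site count of one codon (fractions over non-stop changes)."""
    aa = _TABLE.forward_table[codon]
    total = 0.0
    for pos in range(3):
        syn = 0
        valid = 0
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            mut = codon[:pos] + nt + codon[pos + 1 :]
            if mut in STOP_CODONS:
                continue
            valid += 1
            if _TABLE.forward_table[mut] == aa:
                syn += 1
        if valid:
            total += syn / valid
    return total


_SYN_SITES = {c: _codon_syn_sites(c) for c in CODONS}


def _pathway_differences(ca: str, cb: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences averaged over mutation pathways.

    Codons differing at several positions are connected by all orderings of
    the single-nucleotide steps; pathways passing through a stop codon are
    excluded (all-blocked pairs fall back to including them).
    """
    diffs = [k for k in range(3) if ca[k] != cb[k]]
    if not diffs:
        return 0.0, 0.0
    paths = []
    for perm in itertools.permutations(diffs):
        cur = ca
        steps = []
        ok = True
        for pos in perm:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            steps.append((cur, nxt))
            cur = nxt
        if ok:
            paths.append(steps)
    if not paths:  # pragma: no cover - only reachable with stop-adjacent codons
        for perm in itertools.permutations(diffs):
            cur = ca
            steps = []
            for pos in perm:
                nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
                steps.append((cur, nxt))
                cur = nxt
            paths.append(steps)
    sd = nd = 0.0
    for steps in paths:
        for x, y in steps:
            if _TABLE.forward_table.get(x) == _TABLE.forward_table.get(y):
                sd += 1
            else:
                nd += 1
    return sd / len(paths), nd / len(paths)


def _jc_correct(p: float) -> float:
    return -0.75 * np.log(1.0 - 4.0 * p / 3.0)


def _split_codons(cds: str, name: str = "sequence") -> list[str]:
    cds = cds.upper()
    if len(cds) % 3:
        raise ValueError(f"{name}: length {len(cds)} not divisible by 3")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    for i, c in enumerate(codons):
        if c in STOP_CODONS and i < len(codons) - 1:
            raise ValueError(f"{name}: internal stop codon {c} at codon {i}")
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    return codons


def ng86_kaks(cds_a: str | SequenceRecord, cds_b: str | SequenceRecord) -> KaKsResult:
    """Nei–Gojobori (1986) Ka/Ks with equal pathway weighting.

    Synonymous site fractions are averaged over both sequences; difference
    counts average over all stop-free mutational pathways; the
    Jukes–Cantor correction d = −(3/4)·ln(1 − 4p/3) maps the proportions
    ps, pn to Ks, Ka.  Proportions ≥ 3/4 saturate the correction and are
    reported with ``saturated=True`` and NaN distances rather than raising.
    """
    sa = cds_a.sequence if isinstance(cds_a, SequenceRecord) else cds_a
    sb = cds_b.sequence if isinstance(cds_b, SequenceRecord) else cds_b
    ca = _split_codons(sa, "cds_a")
    cb = _split_codons(sb, "cds_b")
    if len(ca) != len(cb):
        raise ValueError(f"CDS lengths differ: {3 * len(ca)} vs {3 * len(cb)}")
    S = sum((_SYN_SITES[x] + _SYN_SITES[y]) / 2.0 for x, y in zip(ca, cb))
    N = 3.0 * len(ca) - S
    Sd = Nd = 0.0
    for x, y in zip(ca, cb):
        ds, dn = _pathway_differences(x, y)
        Sd += ds
        Nd += dn
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    if ps >= 0.75 or pn >= 0.75:
        return KaKsResult(np.nan, np.nan, np.nan, S, N, Sd, Nd, saturated=True)
    ks = _jc_correct(ps)
    ka = _jc_correct(pn)
    omega = ka / ks if ks > 0 else np.nan
    return KaKsResult(ka, ks, omega, S, N, Sd, Nd)


# ---------------------------------------------------------------------------
# Codon model
# ---------------------------------------------------------------------------

def equal_codon_frequencies() -> np.ndarray:
    return np.full(_NCOD, 1.0 / _NCOD)


def f3x4_frequencies(codon_sequences: Sequence[str], pseudocount: float = 0.5) -> np.ndarray:
    """F3x4 codon frequencies: position-specific nucleotide compositions.

    A small pseudocount keeps every sense codon's frequency positive even
    when a nucleotide is absent at some codon position.
    """
    counts = np.full((3, 4), pseudocount)
    idx = {nt: i for i, nt in enumerate("ACGT")}
    for seq in codon_sequences:
        seq = seq.upper()
        for i, nt in enumerate(seq):
            if nt in idx:
                counts[i % 3, idx[nt]] += 1
    freqs = counts / counts.sum(axis=1, keepdims=True)
    pi = np.array(
        [freqs[0, idx[c[0]]] * freqs[1, idx[c[1]]] * freqs[2, idx[c[2]]] for c in CODONS]
    )
    return pi / pi.sum()


@dataclass
class CodonModel:
    """Branch-site model A parameter bundle.

    ``omega_classes`` maps site class → (background ω, foreground ω);
    proportions follow the model-A constraint p2a = p0·p2/(p0+p1),
    p2b = p1·p2/(p0+p1) with p2 = 1 − p0 − p1.
    """

    kappa: float
    omega0: float
    omega2: float
    p0: float
    p1: float
    pi: np.ndarray = field(default_factory=equal_codon_frequencies)

    def __post_init__(self) -> None:
        if not 0 < self.omega0 < 1:
            raise ValueError("omega0 must lie in (0, 1)")
        if self.omega2 < 1:
            raise ValueError("omega2 must be >= 1")
        if self.p0 < 0 or self.p1 < 0 or self.p0 + self.p1 > 1 + 1e-12:
            raise ValueError("invalid class proportions")
        self.pi = np.asarray(self.pi, dtype=float)
        if abs(self.pi.sum() - 1.0) > 1e-8 or (self.pi <= 0).any():
            raise ValueError("codon frequencies must be positive and sum to 1")

    @property
    def proportions(self) -> np.ndarray:
        p2 = max(1.0 - self.p0 - self.p1, 0.0)
        denom = self.p0 + self.p1
        p2a = p2 * self.p0 / denom
        p2b = p2 * self.p1 / denom
        return np.array([self.p0, self.p1, p2a, p2b])

    @property
    def omega_classes(self) -> list[tuple[float, float]]:
        return [
            (self.omega0, self.omega0),
            (1.0, 1.0),
            (self.omega0, self.omega2),
            (1.0, self.omega2),
        ]


def build_generator(kappa: float, omega: float, pi: np.ndarray) -> np.ndarray:
    """Unnormalized codon rate matrix for one ω (rows sum to zero)."""
    q = np.zeros((_NCOD, _NCOD))
    rate = np.where(_SINGLE_TS, kappa, 1.0) * np.where(_SINGLE_SYN, 1.0, omega)
    q[_SINGLE] = (rate * pi[None, :])[_SINGLE]
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def mixture_mean_rate(model: CodonModel, background: bool = True) -> float:
    """Expected substitutions/codon/unit time under the site-class mixture.

    The flow rate is linear in ω (rate(ω) = syn flow + ω · nonsyn flow), so
    the mixture average needs only two weighted sums over codon pairs.
    """
    pij = np.outer(model.pi, model.pi) * np.where(_SINGLE_TS, model.kappa, 1.0)
    syn_flow = float(pij[_SINGLE & _SINGLE_SYN].sum())
    non_flow = float(pij[_SINGLE & ~_SINGLE_SYN].sum())
    total = 0.0
    for p, (wb, wf) in zip(model.proportions, model.omega_classes):
        w = wb if background else wf
        total += p * (syn_flow + w * non_flow)
    return total


class _EigGenerator:
    """Spectral form of a reversible generator for fast P(t) = exp(Qt)."""

    def __init__(self, q: np.ndarray, pi: np.ndarray):
        sq = np.sqrt(pi)
        b = (q * sq[:, None]) / sq[None, :]
        b = (b + b.T) / 2.0  # symmetrize against round-off
        lam, u = np.linalg.eigh(b)
        self.lam = lam
        self.left = u / sq[:, None]  # rows scaled: P = left @ diag(e^{lam t}) @ right
        self.right = u.T * sq[None, :]

    def expm(self, t: float) -> np.ndarray:
        p = (self.left * np.exp(self.lam * t)) @ self.right
        np.clip(p, 0.0, None, out=p)
        p /= p.sum(axis=1, keepdims=True)
        return p

    def expm_many(self, ts: np.ndarray) -> np.ndarray:
        """Batched P(t) for an array of branch lengths, shape (nt, 61, 61)."""
        e = np.exp(np.outer(ts, self.lam))
        p = (self.left[None, :, :] * e[:, None, :]) @ self.right
        np.clip(p, 0.0, None, out=p)
        p /= p.sum(axis=2, keepdims=True)
        return p


def transition_matrices(
    model: CodonModel, scale: float = 1.0
) -> dict[float, _EigGenerator]:
    """Eigendecompositions for each distinct ω of the model, rate-normalized.

    The common normalization uses the background mixture so that one unit
    of branch length is one expected substitution per codon on background
    branches under the fitted class mix.
    """
    mu = mixture_mean_rate(model, background=True)
    out = {}
    for w in {model.omega0, 1.0, model.omega2}:
        q = build_generator(model.kappa, w, model.pi) / mu
        out[w] = _EigGenerator(q * scale, model.pi)
    return out


# ---------------------------------------------------------------------------
# Tree plumbing and pruning
# ---------------------------------------------------------------------------

class _TreeArrays:
    """Rooted traversal of an (un)rooted tree, re-rooted at the foreground
    branch's parent so the foreground edge hangs directly off the root."""

    def __init__(self, tree, taxon_order: list[str], foreground: str | None):
        import dendropy

        # adjacency with branch lengths
        nodes = list(tree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        self.label = {}
        adj: dict[int, list[tuple[int, float]]] = {i: [] for i in range(len(nodes))}
        fg_node = None
        for nd in nodes:
            i = index[id(nd)]
            name = nd.taxon.label if nd.taxon else nd.label
            self.label[i] = name
            if foreground is not None and name == foreground:
                fg_node = i
            for ch in nd.child_nodes():
                j = index[id(ch)]
                ln = ch.edge.length if ch.edge.length is not None else 0.0
                adj[i].append((j, float(ln)))
                adj[j].append((i, float(ln)))
        if foreground is not None and fg_node is None:
            raise KeyError(f"foreground branch {foreground!r} not found in tree")
        # root at the neighbor of fg (its parent in original orientation) or
        # at the original seed when no foreground is designated
        if fg_node is not None:
            parent = None
            for nd in nodes:
                if index[id(nd)] == fg_node and nd.parent_node is not None:
                    parent = index[id(nd.parent_node)]
            root = parent if parent is not None else adj[fg_node][0][0]
        else:
            root = 0
        # orient edges away from root; edges get dense indices for batched P(t)
        self.children: dict[int, list[tuple[int, int, bool]]] = {}
        lengths: list[float] = []
        seen = {root}
        queue = [root]
        while queue:
            u = queue.pop()
            self.children[u] = []
            for v, ln in adj[u]:
                if v in seen:
                    continue
                seen.add(v)
                self.children[u].append((v, len(lengths), v == fg_node))
                lengths.append(ln)
                queue.append(v)
        self.edge_lengths = np.array(lengths)
        self.root = root
        self.leaf_index = {}
        for i, lbl in self.label.items():
            if not self.children.get(i):
                if lbl not in taxon_order:
                    raise KeyError(f"tree leaf {lbl!r} missing from alignment")
                self.leaf_index[i] = taxon_order.index(lbl)
        if set(self.leaf_index.values()) != set(range(len(taxon_order))):
            raise ValueError("tree leaves and alignment ids do not match")
        # postorder over internal nodes
        self.postorder: list[int] = []

        def visit(u: int) -> None:
            for v, _, _ in self.children[u]:
                if self.children.get(v):
                    visit(v)
            self.postorder.append(u)

        visit(root)
        self.branch_lengths = self.edge_lengths


def _encode_codon_matrix(records: Sequence[SequenceRecord]) -> tuple[list[str], np.ndarray]:
    ids = [r.id for r in records]
    rows = []
    for r in records:
        codons = _split_codons(r.sequence, r.id)
        rows.append([CODON_INDEX[c] for c in codons])
    lens = {len(r) for r in rows}
    if len(lens) != 1:
        raise ValueError("aligned CDS rows differ in codon length")
    return ids, np.array(rows, dtype=np.int32)


class BranchSiteEngine:
    """Pattern-compressed pruning likelihood for branch-site model A.

    Partial likelihoods under the two background regimes (ω0 and 1) are
    shared between site classes; the four classes differ only in the
    transition matrix applied on the foreground edge, which hangs off the
    root by construction.
    """

    def __init__(self, records: Sequence[SequenceRecord], tree, foreground: str | None):
        self.ids, states = _encode_codon_matrix(records)
        patterns, inverse, counts = np.unique(
            states.T, axis=0, return_inverse=True, return_counts=True
        )
        self.patterns = patterns.T  # (ntaxa, npatterns)
        self.weights = counts.astype(float)
        self.n_sites = states.shape[1]
        self.arrays = _TreeArrays(tree, self.ids, foreground)
        self.codon_rows = ["".join(CODONS[i] for i in row) for row in states]

    def _subtree_partial(self, node: int, pmats: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Partial likelihood column array (61, npat) and per-site log scaling."""
        npat = self.patterns.shape[1]
        total_log = np.zeros(npat)
        prod = np.ones((_NCOD, npat))
        for child, eidx, _ in self.arrays.children[node]:
            p = pmats[eidx]
            if self.arrays.children.get(child):
                part, logs = self._subtree_partial(child, pmats)
                prod *= p @ part
                total_log += logs
            else:
                prod *= p[:, self.patterns[self.arrays.leaf_index[child]]]
        mx = prod.max(axis=0)
        if mx.min() < 1e-120:  # rescale only when underflow threatens
            mx[mx == 0] = 1.0
            prod /= mx
            total_log += np.log(mx)
        return prod, total_log

    def log_likelihood(self, model: CodonModel, scale: float = 1.0) -> float:
        eigs = transition_matrices(model)
        arrays = self.arrays
        root = arrays.root
        npat = self.patterns.shape[1]
        ts = arrays.edge_lengths * scale
        # root children partials per background omega, fg child separated
        fg_entry = None
        for entry in arrays.children[root]:
            if entry[2]:
                fg_entry = entry
        # background matrices for every edge; omega2 only acts on the fg edge
        pmats = {w: eigs[w].expm_many(ts) for w in (model.omega0, 1.0)}
        if model.omega2 not in pmats:
            if fg_entry is not None:
                fg_p = eigs[model.omega2].expm(float(ts[fg_entry[1]]))
                full = np.zeros((len(ts), _NCOD, _NCOD))
                full[fg_entry[1]] = fg_p
                pmats[model.omega2] = full
            else:
                pmats[model.omega2] = pmats[1.0]
        per_bg: dict[float, tuple[np.ndarray, np.ndarray, object, np.ndarray]] = {}
        for wb in {model.omega0, 1.0}:
            pm = pmats[wb]
            rest = np.ones((_NCOD, npat))
            rest_log = np.zeros(npat)
            fg_part = None
            fg_log = np.zeros(npat)
            for child, eidx, is_fg in arrays.children[root]:
                if arrays.children.get(child):
                    part, logs = self._subtree_partial(child, pm)
                else:
                    part, logs = None, np.zeros(npat)
                if is_fg:
                    # postpone the foreground edge matrix; keep raw subtree partial
                    fg_part = ("leaf", child) if part is None else ("internal", part)
                    fg_log = logs
                else:
                    p = pm[eidx]
                    if part is None:
                        rest *= p[:, self.patterns[arrays.leaf_index[child]]]
                    else:
                        rest *= p @ part
                        rest_log += logs
            per_bg[wb] = (rest, rest_log, fg_part, fg_log)
        comps = []
        for prob, (wb, wf) in zip(model.proportions, model.omega_classes):
            rest, rest_log, fg_part, fg_log = per_bg[wb]
            if fg_entry is not None:
                fg_eidx = fg_entry[1]
                pf = pmats[wf][fg_eidx]
                if fg_part[0] == "leaf":
                    contrib = pf[:, self.patterns[arrays.leaf_index[fg_part[1]]]]
                else:
                    contrib = pf @ fg_part[1]
                total = rest * contrib
                logs = rest_log + fg_log
            else:
                total = rest
                logs = rest_log
            lsite = model.pi @ total  # (npat,)
            comps.append((prob, lsite, logs))
        # combine mixture components in log space
        all_logs = np.stack([logs for _, _, logs in comps])
        base = all_logs.max(axis=0)
        mix = np.zeros(npat)
        for prob, lsite, logs in comps:
            mix += prob * lsite * np.exp(logs - base)
        if (mix <= 0).any():
            raise FloatingPointError("zero site likelihood under all site classes")
        return float((self.weights * (np.log(mix) + base)).sum())


def codon_log_likelihood(
    alignment: Sequence[SequenceRecord],
    tree,
    model: CodonModel,
    foreground: str | None = None,
    scale: float = 1.0,
) -> float:
    """Felsenstein-pruning log-likelihood of a codon alignment under model A.

    With ``foreground=None`` every branch is background, which reduces the
    model to a site-class mixture shared by all lineages.
    """
    engine = BranchSiteEngine(alignment, tree, foreground)
    return engine.log_likelihood(model, scale)


# ---------------------------------------------------------------------------
# Branch-site fit + LRT
# ---------------------------------------------------------------------------

@dataclass
class BranchSiteFit:
    lnL: float
    p0: float
    p1: float
    p2a: float
    p2b: float
    omega0: float
    omega2: float
    kappa: float
    branch_scale: float
    hypothesis: str  # "alternative" | "null"
    foreground: str
    n_evaluations: int = 0


@dataclass(frozen=True)
class LrtResult:
    statistic: float
    df: int
    p_value: float
    foreground: str


_OMEGA2_CAP = 999.0


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def _unpack(theta: np.ndarray, null: bool, pi: np.ndarray) -> tuple[CodonModel, float]:
    kappa = float(np.exp(theta[0]))
    omega0 = float(np.clip(_sigmoid(theta[1]), 1e-6, 1 - 1e-6))
    if null:
        omega2 = 1.0
        rest = theta[2:]
    else:
        omega2 = float(1.0 + (_OMEGA2_CAP - 1.0) * _sigmoid(theta[2]))
        rest = theta[3:]
    p01 = float(np.clip(_sigmoid(rest[0]), 1e-6, 1 - 1e-6))
    ratio = float(np.clip(_sigmoid(rest[1]), 1e-6, 1 - 1e-6))
    p0 = p01 * ratio
    p1 = p01 * (1.0 - ratio)
    scale = float(np.exp(rest[2]))
    return CodonModel(kappa, omega0, omega2, p0, p1, pi), scale


def _initial_branch_lengths(engine: BranchSiteEngine, tree) -> float:
    """Median pairwise codon divergence, a crude overall-depth estimate."""
    rows = engine.codon_rows
    dists = []
    for a, b in itertools.combinations(range(len(rows)), 2):
        ra, rb = rows[a], rows[b]
        p = sum(x != y for x, y in zip(ra, rb)) / max(len(ra), 1)
        p = min(p, 0.70)
        dists.append(_jc_correct(p) * 3.0)
    return float(np.median(dists)) if dists else 0.3


def fit_branch_site_A(
    alignment: Sequence[SequenceRecord],
    tree,
    foreground_branch: str,
    hypothesis: str = "alternative",
    pi: np.ndarray | None = None,
    n_starts: int = 3,
    seed: int = 0,
    _warm_start: BranchSiteFit | None = None,
) -> BranchSiteFit:
    """Maximum-likelihood fit of branch-site model A.

    Free parameters: κ, ω0 ∈ (0,1), ω2 ∈ [1, 999] (fixed at 1 under the
    null), the class proportions (p0, p1), and a global branch-length
    scale applied to the input tree's lengths.  Optimization runs from
    several deterministic starts (including ω2 = 1.5, the conventional
    initialization) with Nelder–Mead exploration and L-BFGS-B polish; the
    best fit is returned.
    """
    if hypothesis not in ("alternative", "null"):
        raise ValueError("hypothesis must be 'alternative' or 'null'")
    null = hypothesis == "null"
    engine = BranchSiteEngine(alignment, tree, foreground_branch)
    if pi is None:
        pi = f3x4_frequencies(engine.codon_rows)
    depth = _initial_branch_lengths(engine, tree)
    total_bl = float(engine.arrays.branch_lengths.sum())
    scale0 = depth / total_bl if total_bl > 0 else 1.0
    evaluations = [0]

    def negloglik(theta: np.ndarray) -> float:
        evaluations[0] += 1
        try:
            model, scale = _unpack(np.asarray(theta, float), null, pi)
            return -engine.log_likelihood(model, scale)
        except (FloatingPointError, ValueError, OverflowError):
            return 1e12

    def pack(kappa, w0, w2, p01, ratio, scale) -> np.ndarray:
        th = [np.log(kappa), _logit(np.clip(w0, 1e-5, 1 - 1e-5))]
        if not null:
            w2 = min(max(w2, 1.0 + 1e-4), _OMEGA2_CAP - 1e-3)
            th.append(_logit((w2 - 1.0) / (_OMEGA2_CAP - 1.0)))
        th += [_logit(np.clip(p01, 1e-5, 1 - 1e-5)),
               _logit(np.clip(ratio, 1e-5, 1 - 1e-5)), np.log(scale)]
        return np.array(th)

    base_starts = [
        (2.0, 0.5, 1.5, 0.85, 0.55, scale0),
        (1.0, 0.2, 4.0, 0.70, 0.50, scale0),
        (4.0, 0.8, 1.5, 0.95, 0.60, scale0),
    ]
    starts = [pack(*s) for s in base_starts[: max(n_starts, 1)]]
    if _warm_start is not None:
        w = _warm_start
        p01 = w.p0 + w.p1
        ratio = w.p0 / p01 if p01 > 0 else 0.5
        if null:
            starts.insert(0, pack(w.kappa, w.omega0, 1.0, p01, ratio, w.branch_scale))
        else:
            # never seed omega2 at the boundary: a null-like start traps the
            # alternative fit at omega2 = 1
            starts.insert(0, pack(w.kappa, w.omega0, max(w.omega2, 1.8), p01,
                                  ratio, w.branch_scale))

    runs = []
    for th in starts:
        r = optimize.minimize(
            negloglik, th, method="L-BFGS-B",
            options={"maxiter": 60, "maxfun": 400, "ftol": 1e-10},
        )
        runs.append(r)
    res = min(runs, key=lambda r: r.fun)
    if not np.isfinite(res.fun) or res.fun >= 1e11:
        # quasi-Newton failed everywhere; fall back to derivative-free search
        res = min(
            (
                optimize.minimize(
                    negloglik, th, method="Nelder-Mead",
                    options={"maxfev": 500, "xatol": 1e-5, "fatol": 1e-7},
                )
                for th in starts
            ),
            key=lambda r: r.fun,
        )
    if not np.isfinite(res.fun) or res.fun >= 1e11:
        raise RuntimeError(
            f"branch-site optimization failed to converge after {len(starts)} starts "
            f"(best objective {res.fun!r})"
        )
    model, scale = _unpack(res.x, null, pi)
    p0, p1, p2a, p2b = model.proportions
    return BranchSiteFit(
        lnL=-float(res.fun),
        p0=p0, p1=p1, p2a=p2a, p2b=p2b,
        omega0=model.omega0,
        omega2=model.omega2,
        kappa=model.kappa,
        branch_scale=scale,
        hypothesis=hypothesis,
        foreground=foreground_branch,
        n_evaluations=evaluations[0],
    )


def branch_site_lrt(
    alignment: Sequence[SequenceRecord],
    tree,
    foreground_branch: str,
    seed: int = 0,
) -> tuple[BranchSiteFit, BranchSiteFit, LrtResult]:
    """Fit both hypotheses and run the LRT, guarding optimizer asymmetry.

    The null is fitted first; the alternative is warm-started from it.  If
    the resulting statistic is positive, the null is re-polished from the
    alternative's parameters (with ω2 pinned at 1) so a sloppy null
    optimum cannot masquerade as selection signal.
    """
    null = fit_branch_site_A(
        alignment, tree, foreground_branch, "null", seed=seed, n_starts=2
    )
    alt = fit_branch_site_A(
        alignment, tree, foreground_branch, "alternative", seed=seed,
        n_starts=1, _warm_start=null,
    )
    if alt.lnL > null.lnL + 1.0:  # only near-significant outcomes need the guard
        null2 = fit_branch_site_A(
            alignment, tree, foreground_branch, "null", seed=seed,
            n_starts=1, _warm_start=alt,
        )
        if null2.lnL > null.lnL:
            null = null2
    if alt.lnL < null.lnL:
        # omega2 = 1 lies inside the alternative's parameter space, so the
        # null optimum is always attainable by the alternative
        alt = dataclasses.replace(null, omega2=1.0, hypothesis="alternative")
    return alt, null, likelihood_ratio_test(alt, null)


def likelihood_ratio_test(
    fit_alt: BranchSiteFit | float,
    fit_null: BranchSiteFit | float,
    mixture_null: bool = False,
) -> LrtResult:
    """2ΔlnL between nested branch-site fits, referred to χ²₁.

    Accepts either fit objects or raw lnL values.  With
    ``mixture_null=True`` the p-value uses the boundary-respecting 50:50
    mixture of a point mass at zero and χ²₁ instead of plain χ²₁.
    """
    lnl_alt = fit_alt.lnL if isinstance(fit_alt, BranchSiteFit) else float(fit_alt)
    lnl_null = fit_null.lnL if isinstance(fit_null, BranchSiteFit) else float(fit_null)
    fg = fit_alt.foreground if isinstance(fit_alt, BranchSiteFit) else ""
    stat = 2.0 * (lnl_alt - lnl_null)
    if stat < -1e-6:
        raise ValueError(
            f"alternative lnL ({lnl_alt}) below null lnL ({lnl_null}): optimizer failure"
        )
    stat = max(stat, 0.0)
    p = float(stats.chi2.sf(stat, df=1))
    if mixture_null:
        p = 0.5 * p if stat > 0 else 1.0
    return LrtResult(statistic=stat, df=1, p_value=p, foreground=fg)
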