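"""Codon site models of selective pressure: M0, M1a, M2a, M3, M7, M8.

The substitution process is the Goldman–Yang codon model: instantaneous
rates between sense codons differing at one nucleotide are proportional to
the target codon's equilibrium frequency, multiplied by the
transition/transversion ratio kappa for transitions and by omega = dN/dS for
nonsynonymous changes.  Site models let omega vary over sites through a
finite mixture: one ratio (M0), nearly-neutral (M1a), positive-selection
(M2a), three free discrete classes (M3), a discretized beta on [0, 1] (M7),
and beta plus one extra class with omega >= 1 (M8).

Likelihoods are computed by Felsenstein pruning with per-pattern scaling;
fitting is bounded quasi-Newton (L-BFGS-B) on log/logit-transformed
parameters.  Nested pairs M0-M3, M1a-M2a and M7-M8 are compared by
likelihood-ratio tests against chi-square with 4, 2 and 2 degrees of
freedom; positively selected sites are flagged by naive empirical Bayes
(NEB) posteriors at the 0.95 and 0.99 levels.

Positive selection in a sequence set is asserted only when a model's
positive class has omega > 1 AND the corresponding LRT is significant at
0.05; either an omega <= 1 or a nonsignificant LRT rejects it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit, logsumexp
from scipy.stats import beta as beta_dist
from scipy.stats import chi2

from .phylo import Msa, Node, Tree
from .seqcore import SeqcoreError, translate_cds

MODEL_NAMES = ("M0", "M1a", "M2a", "M3", "M7", "M8")
LRT_PAIRS = {
    "M0 vs M3": ("M0", "M3", 4),
    "M1a vs M2a": ("M1a", "M2a", 2),
    "M7 vs M8": ("M7", "M8", 2),
}


class SelectionError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Codon machinery (universal code, 61 sense codons)
# ---------------------------------------------------------------------------

_BASES = "TCAG"
_STOPS = {"TAA", "TAG", "TGA"}
CODONS: list[str] = [
    a + b + c
    for a in _BASES for b in _BASES for c in _BASES
    if a + b + c not in _STOPS
]
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}
N_CODONS = len(CODONS)  # 61

_TRANSITIONS = {frozenset("AG"), frozenset("CT")}


def _codon_aa() -> list[str]:
    from Bio.Data.CodonTable import standard_dna_table

    return [standard_dna_table.forward_table[c] for c in CODONS]


CODON_AA = _codon_aa()

# single-nucleotide-difference pairs: (i, j, is_transition, is_synonymous)
_PAIRS: list[tuple[int, int, bool, bool]] = []
for _i in range(N_CODONS):
    for _j in range(_i + 1, N_CODONS):
        diff = [k for k in range(3) if CODONS[_i][k] != CODONS[_j][k]]
        if len(diff) == 1:
            k = diff[0]
            ts = frozenset((CODONS[_i][k], CODONS[_j][k])) in _TRANSITIONS
            syn = CODON_AA[_i] == CODON_AA[_j]
            _PAIRS.append((_i, _j, ts, syn))

_PAIR_I = np.array([p[0] for p in _PAIRS])
_PAIR_J = np.array([p[1] for p in _PAIRS])
_PAIR_TS = np.array([p[2] for p in _PAIRS])
_PAIR_SYN = np.array([p[3] for p in _PAIRS])


def gy94_Q(
    kappa: float, omega: float, pi: np.ndarray, scale: bool = True
) -> np.ndarray:
    """Goldman–Yang generator over the 61 sense codons.

    Off-diagonal rate i->j is zero for multi-nucleotide changes and
    otherwise pi_j times 1, kappa, omega or omega*kappa for synonymous
    transversions, synonymous transitions, nonsynonymous transversions and
    nonsynonymous transitions.  Rows sum to zero; with ``scale`` the matrix
    is normalized to one expected substitution per unit time.  Codons with
    pi = 0 are isolated (zero rates), i.e. the process is restricted to the
    observed codon set.
    """
    if kappa <= 0 or omega < 0:
        raise SelectionError("need kappa > 0 and omega >= 0")
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (N_CODONS,) or pi.min() < 0 or not np.isclose(pi.sum(), 1):
        raise SelectionError("pi must be a distribution over the 61 codons")
    Q = np.zeros((N_CODONS, N_CODONS))
    factor = np.where(_PAIR_TS, kappa, 1.0) * np.where(_PAIR_SYN, 1.0, omega)
    Q[_PAIR_I, _PAIR_J] = pi[_PAIR_J] * factor
    Q[_PAIR_J, _PAIR_I] = pi[_PAIR_I] * factor
    Q[pi == 0, :] = 0.0
    Q[:, pi == 0] = 0.0
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    if scale:
        rate = -float(pi @ np.diag(Q))
        if rate > 0:
            Q /= rate
    return Q


def class_matrices(
    kappa: float, omegas: Sequence[float], probs: Sequence[float],
    pi: np.ndarray,
) -> list[np.ndarray]:
    """Per-class generators scaled jointly so the mixture's expected rate
    is one substitution per unit time (branch lengths are then in expected
    substitutions per codon)."""
    Qs = [gy94_Q(kappa, w, pi, scale=False) for w in omegas]
    rho = sum(
        p * -float(pi @ np.diag(Q)) for p, Q in zip(probs, Qs)
    )
    if rho <= 0:
        raise SelectionError("mixture has zero expected rate")
    return [Q / rho for Q in Qs]


def _spectral(Q: np.ndarray, pi: np.ndarray):
    """Symmetrized eigendecomposition of a reversible generator."""
    d = np.sqrt(np.where(pi > 0, pi, 1.0))
    B = Q * (d[:, None] / d[None, :])
    B = 0.5 * (B + B.T)
    w, U = np.linalg.eigh(B)
    return w, U, d


def transition_matrix_factory(Q: np.ndarray, pi: np.ndarray):
    """Return P(t) = exp(Qt) as a cheap function of t via one spectral
    decomposition (the model is reversible)."""
    w, U, d = _spectral(Q, pi)

    def P(t: float) -> np.ndarray:
        if t < 0:
            raise SelectionError("negative branch length")
        M = (U * np.exp(w * t)) @ U.T
        M = M * (d[None, :] / d[:, None])
        np.clip(M, 0.0, None, out=M)
        return M

    return P


# ---------------------------------------------------------------------------
# Codon alignments
# ---------------------------------------------------------------------------

@dataclass
class CodonAlignment:
    """In-frame codon alignment over the 61-sense-codon alphabet.

    ``codons`` is (n_taxa, L) of indices into :data:`CODONS`; -1 marks a
    whole-codon gap.  Stop codons are rejected.
    """

    ids: list[str]
    codons: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.codons.ndim != 2 or self.codons.shape[0] != len(self.ids):
            raise SelectionError("codon matrix shape does not match ids")

    @property
    def L(self) -> int:
        return self.codons.shape[1]

    @classmethod
    def from_strings(cls, seqs: Mapping[str, str], **meta) -> "CodonAlignment":
        ids = list(seqs)
        lengths = {len(s) for s in seqs.values()}
        if len(lengths) != 1 or next(iter(lengths)) % 3:
            raise SelectionError("rows must share a length divisible by 3")
        L = next(iter(lengths)) // 3
        mat = np.empty((len(ids), L), dtype=int)
        for r, sid in enumerate(ids):
            s = seqs[sid].upper().replace("U", "T")
            for h in range(L):
                codon = s[3 * h : 3 * h + 3]
                if codon == "---":
                    mat[r, h] = -1
                elif codon in _STOPS:
                    raise SelectionError(f"stop codon in {sid!r} at site {h + 1}")
                elif codon in CODON_INDEX:
                    mat[r, h] = CODON_INDEX[codon]
                else:
                    raise SelectionError(
                        f"bad codon {codon!r} in {sid!r} at site {h + 1} "
                        "(gaps must cover whole codons)"
                    )
        return cls(ids, mat, dict(meta))

    @classmethod
    def from_fasta(cls, path: str | Path) -> "CodonAlignment":
        from .seqcore import read_cds_fasta

        return cls.from_strings(read_cds_fasta(path))

    def to_strings(self) -> dict[str, str]:
        out = {}
        for r, sid in enumerate(self.ids):
            out[sid] = "".join(
                "---" if k < 0 else CODONS[k] for k in self.codons[r]
            )
        return out

    def f3x4(self) -> np.ndarray:
        """Codon frequencies from per-position nucleotide frequencies
        (codeml's F3x4), zeroed at stops and renormalized."""
        counts = np.zeros((3, 4))
        base_idx = {b: k for k, b in enumerate(_BASES)}
        for r in range(self.codons.shape[0]):
            for k in self.codons[r]:
                if k >= 0:
                    for pos, b in enumerate(CODONS[k]):
                        counts[pos, base_idx[b]] += 1
        freqs = counts / counts.sum(axis=1, keepdims=True)
        pi = np.array([
            freqs[0, base_idx[c[0]]]
            * freqs[1, base_idx[c[1]]]
            * freqs[2, base_idx[c[2]]]
            for c in CODONS
        ])
        total = pi.sum()
        if total <= 0:
            raise SelectionError("degenerate codon frequencies")
        return pi / total

    def uniform_pi(self) -> np.ndarray:
        return np.full(N_CODONS, 1.0 / N_CODONS)


def build_codon_alignment(
    protein_msa: Msa, cds: Mapping[str, str], drop_gapped: bool = True
) -> CodonAlignment:
    """Thread coding sequences onto a protein alignment.

    Each protein row's gaps are expanded to codon-triplet gaps.  The CDS may
    include signal-peptide codons (and a stop codon): its translation must
    equal the de-gapped row or end with it.  With ``drop_gapped`` (cleandata
    behavior) codon columns containing any gap are removed; the count is
    recorded in the alignment metadata.
    """
    rows: dict[str, str] = {}
    for sid, row in protein_msa.rows.items():
        if sid not in cds:
            raise SelectionError(f"no CDS for aligned row {sid!r}")
        seq = cds[sid].upper().replace("U", "T")
        if len(seq) % 3:
            raise SelectionError(f"CDS {sid!r}: length not divisible by 3")
        trans = translate_cds(seq, sid)
        if seq[-3:] in _STOPS:
            seq = seq[:-3]
        prot = row.replace("-", "")
        if trans == prot:
            offset = 0
        elif trans.endswith(prot):
            offset = len(trans) - len(prot)
        else:
            upto = min(len(trans), len(prot))
            pos = next(
                (k for k in range(upto) if trans[k] != prot[k]), upto
            )
            raise SelectionError(
                f"{sid!r}: CDS translation does not match aligned protein "
                f"(first mismatch at residue {pos + 1})"
            )
        codons = seq[3 * offset :]
        out = []
        k = 0
        for ch in row:
            if ch == "-":
                out.append("---")
            else:
                out.append(codons[3 * k : 3 * k + 3])
                k += 1
        rows[sid] = "".join(out)
    aln = CodonAlignment.from_strings(rows)
    if drop_gapped:
        keep = ~np.any(aln.codons < 0, axis=0)
        dropped = int((~keep).sum())
        aln = CodonAlignment(
            aln.ids, aln.codons[:, keep],
            {"cleandata": True, "dropped_gapped_sites": dropped},
        )
    else:
        aln.meta.update({"cleandata": False, "dropped_gapped_sites": 0})
    return aln


# ---------------------------------------------------------------------------
# Model specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CodonModelSpec:
    """A site-model name plus structural knobs (beta category count)."""

    name: str
    ncat_beta: int = 10

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise SelectionError(f"unknown model {self.name!r}")


def beta_categories(p: float, q: float, ncat: int) -> np.ndarray:
    """Median-of-equal-probability-bin discretization of Beta(p, q)."""
    quantiles = (np.arange(ncat) + 0.5) / ncat
    return beta_dist.ppf(quantiles, p, q)


def class_structure(
    spec: CodonModelSpec, params: Mapping[str, float | Sequence[float]]
) -> tuple[np.ndarray, np.ndarray]:
    """Omega values and proportions of the site classes of a model."""
    name = spec.name
    if name == "M0":
        return np.array([params["omega"]]), np.array([1.0])
    if name == "M1a":
        p0 = float(params["p0"])
        return np.array([params["omega0"], 1.0]), np.array([p0, 1 - p0])
    if name == "M2a":
        p0, p1 = float(params["p0"]), float(params["p1"])
        return (
            np.array([params["omega0"], 1.0, params["omega2"]]),
            np.array([p0, p1, 1 - p0 - p1]),
        )
    if name == "M3":
        probs = np.asarray(params["probs"], dtype=float)
        omegas = np.asarray(params["omegas"], dtype=float)
        return omegas, probs
    if name == "M7":
        cats = beta_categories(params["p"], params["q"], spec.ncat_beta)
        return cats, np.full(spec.ncat_beta, 1.0 / spec.ncat_beta)
    if name == "M8":
        p0 = float(params["p0"])
        cats = beta_categories(params["p"], params["q"], spec.ncat_beta)
        omegas = np.append(cats, params["omega_s"])
        probs = np.append(
            np.full(spec.ncat_beta, p0 / spec.ncat_beta), 1 - p0
        )
        return omegas, probs
    raise SelectionError(name)


# ---------------------------------------------------------------------------
# Likelihood by pruning
# ---------------------------------------------------------------------------

def _patterns(codons: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unique site patterns, their counts, and site -> pattern index."""
    patterns, inverse, counts = np.unique(
        codons, axis=1, return_inverse=True, return_counts=True
    )
    return patterns, counts, inverse.ravel()


def _class_site_logliks(
    patterns: np.ndarray,
    row_of: Mapping[str, int],
    tree: Tree,
    Qs: Sequence[np.ndarray],
    pi: np.ndarray,
) -> np.ndarray:
    """log f(pattern | class) by scaled Felsenstein pruning; (n_pat, K)."""
    n_pat = patterns.shape[1]
    support = pi > 0
    S = int(support.sum())
    sup_idx = np.flatnonzero(support)
    remap = -np.ones(N_CODONS, dtype=int)
    remap[sup_idx] = np.arange(S)
    pi_s = pi[sup_idx]

    leaf_onehot: dict[str, np.ndarray] = {}
    for name, r in row_of.items():
        M = np.zeros((n_pat, S))
        for h in range(n_pat):
            k = patterns[r, h]
            if k < 0:
                M[h, :] = 1.0
            else:
                ks = remap[k]
                if ks < 0:
                    raise SelectionError(
                        f"codon {CODONS[k]} observed in {name!r} has zero "
                        "equilibrium frequency"
                    )
                M[h, ks] = 1.0
        leaf_onehot[name] = M

    out = np.empty((n_pat, len(Qs)))
    for kcl, Q in enumerate(Qs):
        Pfun = transition_matrix_factory(Q[np.ix_(sup_idx, sup_idx)], pi_s)
        logscale = np.zeros(n_pat)
        partials: dict[int, np.ndarray] = {}
        for node in tree.postorder():
            if node.is_leaf:
                partials[id(node)] = leaf_onehot[node.name]
                continue
            part = np.ones((n_pat, S))
            for ch in node.children:
                t = ch.length if ch.length is not None else 0.0
                part *= partials.pop(id(ch)) @ Pfun(t).T
            if node is not tree.root:
                m = part.max(axis=1)
                m[m == 0] = 1.0
                part /= m[:, None]
                logscale += np.log(m)
            partials[id(node)] = part
        f = partials[id(tree.root)] @ pi_s
        if np.any(f <= 0):
            f = np.clip(f, 1e-300, None)
        out[:, kcl] = np.log(f) + logscale
    return out


def site_loglik(
    aln: CodonAlignment,
    tree: Tree,
    spec: CodonModelSpec,
    params: Mapping[str, float | Sequence[float]],
    pi: np.ndarray | None = None,
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Log-likelihood of a site model on a fixed tree.

    Returns (lnL, per-site per-class log-likelihoods (L, K), class omegas,
    class proportions).  Sites are independent: lnL is the sum over sites of
    the log mixture density.
    """
    if set(aln.ids) != tree.leaf_names:
        raise SelectionError("tree leaf set does not match alignment ids")
    if not np.isfinite(float(params.get("kappa", np.nan))):
        raise SelectionError("params must include kappa")
    pi = aln.f3x4() if pi is None else np.asarray(pi, dtype=float)
    omegas, probs = class_structure(spec, params)
    Qs = class_matrices(float(params["kappa"]), omegas, probs, pi)
    patterns, counts, site_of = _patterns(aln.codons)
    row_of = {sid: r for r, sid in enumerate(aln.ids)}
    pat_logliks = _class_site_logliks(patterns, row_of, tree, Qs, pi)
    pat_mix = logsumexp(pat_logliks + np.log(probs)[None, :], axis=1)
    lnl = float(counts @ pat_mix)
    if not np.isfinite(lnl):
        raise SelectionError("non-finite log-likelihood")
    return lnl, pat_logliks[site_of], omegas, probs


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

_LOGIT_BOUND = (-15.0, 15.0)


def _free_param_layout(spec: CodonModelSpec) -> list[tuple[str, str, tuple]]:
    """(key, transform, bounds) for the free class parameters of a model."""
    log_omega = ("log", (np.log(1e-4), np.log(99.0)))
    log_beta = ("log", (np.log(5e-3), np.log(99.0)))
    sig = ("sigmoid", _LOGIT_BOUND)
    omega_gt1 = ("one_plus_exp", (-12.0, np.log(50.0)))
    name = spec.name
    layout = [("kappa", "log", (np.log(0.05), np.log(50.0)))]
    if name == "M0":
        layout += [("omega", *log_omega)]
    elif name == "M1a":
        layout += [("p0", *sig), ("omega0", *sig)]
    elif name == "M2a":
        layout += [("s0", *sig), ("s1", *sig), ("omega0", *sig),
                   ("omega2", *omega_gt1)]
    elif name == "M3":
        layout += [("s0", *sig), ("s1", *sig)]
        layout += [(f"omega{k}", *log_omega) for k in range(3)]
    elif name == "M7":
        layout += [("p", *log_beta), ("q", *log_beta)]
    elif name == "M8":
        layout += [("s0", *sig), ("p", *log_beta), ("q", *log_beta),
                   ("omega_s", *omega_gt1)]
    return layout


def _forward(value: float, transform: str) -> float:
    if transform == "log":
        return float(np.log(value))
    if transform == "sigmoid":
        return float(logit(np.clip(value, 1e-7, 1 - 1e-7)))
    if transform == "one_plus_exp":
        return float(np.log(max(value - 1.0, 1e-6)))
    raise SelectionError(transform)


def _inverse(x: float, transform: str) -> float:
    if transform == "log":
        return float(np.exp(x))
    if transform == "sigmoid":
        return float(expit(x))
    if transform == "one_plus_exp":
        return 1.0 + float(np.exp(x))
    raise SelectionError(transform)


def _to_params(spec: CodonModelSpec, raw: Mapping[str, float]) -> dict:
    """Raw transformed-free-parameter values -> model parameter dict."""
    name = spec.name
    p = dict(raw)
    if name == "M2a":
        p0 = p.pop("s0")
        p1 = (1 - p0) * p.pop("s1")
        p.update(p0=p0, p1=p1)
    elif name == "M3":
        p1 = p.pop("s0")
        p2 = (1 - p1) * p.pop("s1")
        p["probs"] = [p1, p2, 1 - p1 - p2]
        p["omegas"] = [p.pop(f"omega{k}") for k in range(3)]
    elif name == "M8":
        p["p0"] = p.pop("s0")
    return p


_DEFAULT_START: dict[str, dict[str, float]] = {
    "M0": {"kappa": 2.0, "omega": 0.4},
    "M1a": {"kappa": 2.0, "p0": 0.7, "omega0": 0.2},
    "M2a": {"kappa": 2.0, "s0": 0.6, "s1": 0.75, "omega0": 0.2,
            "omega2": 2.0},
    "M3": {"kappa": 2.0, "s0": 0.4, "s1": 0.5, "omega0": 0.05,
           "omega1": 0.4, "omega2": 1.5},
    "M7": {"kappa": 2.0, "p": 0.5, "q": 1.5},
    "M8": {"kappa": 2.0, "s0": 0.9, "p": 0.5, "q": 1.5, "omega_s": 1.5},
}


@dataclass
class SiteModelFit:
    """A fitted codon site model."""

    model: str
    lnl: float
    kappa: float
    params: dict
    class_omegas: np.ndarray
    class_probs: np.ndarray
    site_class_loglik: np.ndarray  # (L, K) log f(site | class)
    tree: Tree
    pi: np.ndarray
    spec: CodonModelSpec
    meta: dict = field(default_factory=dict)

    @property
    def positive_class_omega(self) -> float | None:
        """The omega estimate of the model's positive-selection class: the
        highest class omega for M3, omega2 for M2a, omega_s for M8, the
        single omega for M0; None for models capped at omega = 1."""
        if self.model == "M2a":
            return float(self.params["omega2"])
        if self.model == "M8":
            return float(self.params["omega_s"])
        if self.model == "M3":
            return float(np.max(self.params["omegas"]))
        if self.model == "M0":
            return float(self.params["omega"])
        return None

    def site_posteriors(self) -> np.ndarray:
        """NEB posterior P(class | site), rows summing to one; (L, K)."""
        logpost = self.site_class_loglik + np.log(self.class_probs)[None, :]
        logpost -= logsumexp(logpost, axis=1, keepdims=True)
        return np.exp(logpost)


def _branch_nodes(tree: Tree) -> list[Node]:
    return [n for n in tree.postorder() if n is not tree.root]


def fit_model(
    aln: CodonAlignment,
    tree: Tree,
    spec: CodonModelSpec | str,
    *,
    pi: np.ndarray | None = None,
    optimize_branch_lengths: bool | None = None,
    start: Mapping[str, float] | Sequence[Mapping[str, float]] | None = None,
    n_starts: int = 1,
    seeds: Sequence[int] = (1, 2, 3),
    tol: float = 1e-6,
) -> SiteModelFit:
    """Maximize the site-model likelihood over kappa, class parameters and,
    optionally, branch lengths.

    Branch lengths are optimized by default only under M0; other models are
    usually fitted on the M0 tree (see :func:`fit_all_models`).  ``start``
    warm-starts the free parameters (raw scale, keys as in the model's
    layout); a sequence of dicts runs one optimization per start and keeps
    the best optimum.  ``n_starts > 1`` additionally adds seed-perturbed
    restarts from the fixed seed list.  With fixed inputs the fit is
    deterministic.
    """
    if isinstance(spec, str):
        spec = CodonModelSpec(spec)
    if aln.L == 0:
        raise SelectionError("empty alignment")
    pi = aln.f3x4() if pi is None else np.asarray(pi, dtype=float)
    if optimize_branch_lengths is None:
        optimize_branch_lengths = spec.name == "M0"
    work_tree = tree.copy()
    layout = _free_param_layout(spec)
    if start is None:
        start_dicts: list[Mapping[str, float]] = [{}]
    elif isinstance(start, Mapping):
        start_dicts = [start]
    else:
        start_dicts = list(start) or [{}]
    x0s = []
    for sd in start_dicts:
        base = dict(_DEFAULT_START[spec.name])
        base.update(sd)
        x0s.append(np.array([_forward(base[k], tr) for k, tr, _ in layout]))
    bounds = [b for _, _, b in layout]
    branches = _branch_nodes(work_tree) if optimize_branch_lengths else []
    bl_bounds = (np.log(1e-7), np.log(30.0))
    if branches:
        bl0 = np.log([max(n.length or 0.05, 1e-6) for n in branches])
        x0s = [np.concatenate([x, bl0]) for x in x0s]
        bounds = bounds + [bl_bounds] * len(branches)

    patterns, counts, site_of = _patterns(aln.codons)
    row_of = {sid: r for r, sid in enumerate(aln.ids)}
    n_free = len(layout)

    def unpack(x: np.ndarray) -> dict:
        raw = {
            key: _inverse(x[i], tr) for i, (key, tr, _) in enumerate(layout)
        }
        return _to_params(spec, raw)

    def neg_lnl(x: np.ndarray) -> float:
        params = unpack(x)
        for node, lx in zip(branches, x[n_free:]):
            node.length = float(np.exp(lx))
        omegas, probs = class_structure(spec, params)
        try:
            Qs = class_matrices(params["kappa"], omegas, probs, pi)
            pls = _class_site_logliks(patterns, row_of, work_tree, Qs, pi)
        except (SelectionError, np.linalg.LinAlgError):
            return 1e12
        mix = logsumexp(pls + np.log(np.maximum(probs, 1e-300))[None, :], axis=1)
        val = float(counts @ mix)
        return -val if np.isfinite(val) else 1e12

    starts = list(x0s)
    if n_starts > 1:
        lo = np.array([b[0] for b in bounds])
        hi = np.array([b[1] for b in bounds])
        for s in seeds[: n_starts - 1]:
            rng = np.random.default_rng(s)
            perturbed = x0s[0].copy()
            perturbed[:n_free] += rng.normal(0, 0.5, size=n_free)
            starts.append(np.clip(perturbed, lo + 1e-6, hi - 1e-6))

    best = None
    for xs in starts:
        res = minimize(
            neg_lnl, xs, method="L-BFGS-B", bounds=bounds,
            options={"ftol": 1e-10, "gtol": 1e-7, "eps": 1e-6,
                     "maxiter": 500, "maxfun": 20000},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e11:
        raise SelectionError("optimizer failed to find a finite optimum")

    params = unpack(best.x)
    for node, lx in zip(branches, best.x[n_free:]):
        node.length = float(np.exp(lx))
    lnl, site_cls, omegas, probs = site_loglik(
        aln, work_tree, spec, params, pi=pi
    )
    return SiteModelFit(
        model=spec.name,
        lnl=lnl,
        kappa=float(params["kappa"]),
        params=params,
        class_omegas=omegas,
        class_probs=probs,
        site_class_loglik=site_cls,
        tree=work_tree,
        pi=pi,
        spec=spec,
        meta={
            "converged": bool(best.success),
            "nfev": int(best.nfev),
            "optimized_branch_lengths": bool(branches),
            "message": str(best.message),
        },
    )


def _warm_start_for(alt: str, null_fit: SiteModelFit) -> dict[str, float]:
    """Start the alternative model at (a boundary image of) the null MLE so
    the fitted alternative can only improve on the null likelihood."""
    p = null_fit.params
    if alt == "M3":
        w = max(float(p["omega"]), 1e-3)
        return {"kappa": null_fit.kappa, "s0": 1 / 3, "s1": 0.5,
                "omega0": w, "omega1": w, "omega2": w}
    if alt == "M2a":
        p0 = float(p["p0"])
        return {"kappa": null_fit.kappa, "s0": p0,
                "s1": 1 - 1e-6, "omega0": float(p["omega0"]),
                "omega2": 1.0 + 1e-4}
    if alt == "M8":
        return {"kappa": null_fit.kappa, "s0": 1 - 1e-6,
                "p": float(p["p"]), "q": float(p["q"]),
                "omega_s": 1.0 + 1e-4}
    raise SelectionError(alt)


def fit_all_models(
    aln: CodonAlignment,
    tree: Tree,
    models: Sequence[str] = MODEL_NAMES,
    *,
    pi: np.ndarray | None = None,
    ncat_beta: int = 10,
    full_branch_optimization: bool = False,
    n_starts: int = 1,
) -> tuple[dict[str, SiteModelFit], dict[str, "LrtResult"]]:
    """Fit the requested site models and the three nested LRT pairs.

    Branch lengths are estimated once under M0 and reused for the other
    models (enable ``full_branch_optimization`` to refit them per model);
    M2a is warm-started at the M1a optimum, M8 at the M7 optimum, M3 at the
    M0 optimum, which enforces the nesting inequality up to optimizer
    tolerance.
    """
    pi = aln.f3x4() if pi is None else np.asarray(pi, dtype=float)
    fits: dict[str, SiteModelFit] = {}
    m0 = fit_model(aln, tree, CodonModelSpec("M0"), pi=pi,
                   optimize_branch_lengths=True, n_starts=n_starts)
    base_tree = m0.tree
    if "M0" in models:
        fits["M0"] = m0
    opts = dict(pi=pi, n_starts=n_starts,
                optimize_branch_lengths=True if full_branch_optimization else False)
    for name in models:
        if name == "M0" or name in fits:
            continue
        spec = CodonModelSpec(name, ncat_beta=ncat_beta)
        # run both the boundary warm start (which guarantees the nesting
        # inequality) and the default start (which restores search power
        # when the optimum lies away from the null boundary); keep the best
        start: list[Mapping[str, float]] | None = None
        if name == "M3":
            start = [_warm_start_for("M3", m0), {}]
        elif name == "M2a" and "M1a" in fits:
            start = [_warm_start_for("M2a", fits["M1a"]), {}]
        elif name == "M8" and "M7" in fits:
            start = [_warm_start_for("M8", fits["M7"]), {}]
        fits[name] = fit_model(aln, base_tree, spec, start=start, **opts)
    lrts: dict[str, LrtResult] = {}
    for pair, (null, alt, _df) in LRT_PAIRS.items():
        if null in fits and alt in fits:
            lrts[pair] = lrt(fits[null], fits[alt])
    return fits, lrts


# ---------------------------------------------------------------------------
# LRT, NEB, decision rule
# ---------------------------------------------------------------------------

@dataclass
class LrtResult:
    """A likelihood-ratio test between nested site models."""

    pair: str
    stat: float  # 2 * (lnL_alt - lnL_null), floored at 0
    df: int
    p: float


def _pair_name(null: str, alt: str) -> str:
    for pair, (n, a, _) in LRT_PAIRS.items():
        if (n, a) == (null, alt):
            return pair
    raise SelectionError(f"unknown nested pair {null!r} vs {alt!r}")


def lrt(
    fit_null: SiteModelFit | float,
    fit_alt: SiteModelFit | float,
    pair: str | None = None,
    df: int | None = None,
) -> LrtResult:
    """Likelihood-ratio test of a nested model pair.

    Accepts fitted models (pair inferred from their names) or raw
    log-likelihoods with an explicit ``pair``.  2*delta-lnL is floored at
    zero with a warning (a genuinely negative difference signals optimizer
    failure); the p-value is the chi-square upper tail with the pair's
    degrees of freedom (4 for M0-M3, 2 otherwise).
    """
    if isinstance(fit_null, SiteModelFit) and isinstance(fit_alt, SiteModelFit):
        pair = pair or _pair_name(fit_null.model, fit_alt.model)
        l0, l1 = fit_null.lnl, fit_alt.lnl
    else:
        if pair is None:
            raise SelectionError("pair name required with raw log-likelihoods")
        if pair not in LRT_PAIRS:
            raise SelectionError(f"unknown pair {pair!r}")
        l0, l1 = float(fit_null), float(fit_alt)
    df = df if df is not None else LRT_PAIRS[pair][2]
    stat = 2.0 * (l1 - l0)
    if stat < 0:
        if stat < -1e-4:
            warnings.warn(
                f"{pair}: alternative fit worse than null (2dl = {stat:.3g}); "
                "flooring at 0 — check optimizer convergence"
            )
        stat = 0.0
    return LrtResult(pair, stat, df, float(chi2.sf(stat, df)))


def lrt_from_stat(pair: str, stat: float) -> LrtResult:
    """LRT p-value from a precomputed 2*delta-lnL statistic."""
    if pair not in LRT_PAIRS:
        raise SelectionError(f"unknown pair {pair!r}")
    df = LRT_PAIRS[pair][2]
    stat = max(float(stat), 0.0)
    return LrtResult(pair, stat, df, float(chi2.sf(stat, df)))


def neb_sites(
    fit: SiteModelFit, levels: Sequence[float] = (0.95, 0.99)
) -> pd.DataFrame:
    """Naive-empirical-Bayes positive-site table.

    Posterior of each omega class at each site uses the MLEs plugged in;
    the 'posterior' column is the total probability of classes with
    omega > 1.  Returns an empty frame (with a 'reason' attribute) when the
    fitted model has no positive class.
    """
    positive = fit.class_omegas > 1.0
    cols = ["site", "posterior", "level"]
    if not positive.any():
        out = pd.DataFrame(columns=cols)
        out.attrs["reason"] = (
            f"{fit.model}: no site class with omega > 1 "
            f"(max omega {fit.class_omegas.max():.4g})"
        )
        return out
    post = fit.site_posteriors()[:, positive].sum(axis=1)
    levels = sorted(levels)
    rows = []
    for h, pr in enumerate(post):
        level = max((lv for lv in levels if pr >= lv), default=None)
        rows.append((h + 1, float(pr), level))
    df = pd.DataFrame(rows, columns=cols)
    df.attrs["reason"] = None
    return df


@dataclass
class SelectionVerdict:
    """Outcome of the positive-selection decision rule for one sequence set."""

    positive: bool
    ensured_by: list[str]
    detail: dict[str, dict]


def positive_selection_decision(
    fits: Mapping[str, "SiteModelFit | float | None"],
    lrts: Mapping[str, LrtResult],
    alpha: float = 0.05,
) -> SelectionVerdict:
    """Apply the decision rule: positive selection is asserted only when the
    positive-class omega of M3, M2a or M8 exceeds one AND the corresponding
    LRT (M0-M3, M1a-M2a, M7-M8) has p < alpha; it is rejected either by an
    omega not above one or by a nonsignificant LRT.

    ``fits`` maps model names to fitted models, to bare positive-class omega
    values, or to None (omega <= 1 / not applicable).
    """
    def omega_of(name: str) -> float | None:
        f = fits.get(name)
        if f is None:
            return None
        if isinstance(f, SiteModelFit):
            return f.positive_class_omega
        return float(f)

    ensured = []
    detail: dict[str, dict] = {}
    for pair, (null, alt, _df) in LRT_PAIRS.items():
        w = omega_of(alt)
        res = lrts.get(pair)
        ok = w is not None and w > 1.0 and res is not None and res.p < alpha
        detail[pair] = {
            "omega_positive": w,
            "p": res.p if res is not None else None,
            "ensures": ok,
        }
        if ok:
            ensured.append(pair)
    return SelectionVerdict(bool(ensured), ensured, detail)
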