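"""Synthetic data with the statistical structure every pipeline stage assumes.

Four generators cover the pipeline's inputs: Yule trees with exponential
branch lengths; codon alignments evolved under a chosen site model with the
true per-site omega class recorded; LP-like proteins built from a fixed
synthetic reference with the catalytic anchors planted or ablated per
requested type and signal peptides prepended; and gene models with introns
planted at known homologous codon positions/phases, with optional positional
jitter emulating intron sliding.  Every generator is reproducible from its
seed and emits a truth table for round-trip recovery tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .phylo import Msa, Node, Tree
from .seqcore import GeneModel, ProteinRecord
from .selection import (
    CODONS,
    CODON_AA,
    CODON_INDEX,
    N_CODONS,
    CodonAlignment,
    CodonModelSpec,
    class_matrices,
    class_structure,
    transition_matrix_factory,
)

AA20 = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def sim_tree(seed: int, n_taxa: int, mean_branch: float = 0.1) -> Tree:
    """Yule (pure-birth) topology with iid exponential branch lengths.

    Leaves are named t1..tN.  ``mean_branch = 0`` produces a degenerate
    star-like tree (all lengths zero) and warns.
    """
    if n_taxa < 3:
        raise ValueError("need n_taxa >= 3")
    rng = np.random.default_rng(seed)
    tips = [Node(name=f"t{i + 1}") for i in range(2)]
    root = Node()
    for t in tips:
        root.add(t)
    count = 2
    while count < n_taxa:
        split = tips[rng.integers(len(tips))]
        count += 1
        a, b = Node(name=split.name), Node(name=f"t{count}")
        split.name = None
        split.add(a)
        split.add(b)
        tips.remove(split)
        tips.extend([a, b])
    if mean_branch <= 0:
        warnings.warn("mean_branch <= 0: degenerate star-like tree")
    for node in root.postorder():
        if node is not root:
            node.length = (
                float(rng.exponential(mean_branch)) if mean_branch > 0 else 0.0
            )
    return Tree(root)


# ---------------------------------------------------------------------------
# Codon alignments
# ---------------------------------------------------------------------------

def sim_codon_alignment(
    tree: Tree,
    spec: CodonModelSpec | str,
    params: Mapping[str, float | Sequence[float]],
    L: int,
    seed: int,
    pi: np.ndarray | None = None,
) -> tuple[CodonAlignment, np.ndarray]:
    """Evolve a codon alignment along ``tree`` under a site model.

    Each site draws an omega class from the model's mixture (recorded in the
    returned truth array), the root codon from pi, and descendant states
    through exp(Q_class * t) per branch.  Returns (alignment, true class
    index per site).
    """
    if isinstance(spec, str):
        spec = CodonModelSpec(spec)
    rng = np.random.default_rng(seed)
    pi = np.full(N_CODONS, 1.0 / N_CODONS) if pi is None else np.asarray(pi)
    omegas, probs = class_structure(spec, params)
    Qs = class_matrices(float(params["kappa"]), omegas, probs, pi)
    classes = rng.choice(len(probs), size=L, p=probs / probs.sum())
    states = {id(tree.root): rng.choice(N_CODONS, size=L, p=pi / pi.sum())}
    Pfuns = [transition_matrix_factory(Q, pi) for Q in Qs]

    for node in tree.preorder():
        if node is tree.root:
            continue
        parent_state = states[id(node.parent)]
        child = np.empty(L, dtype=int)
        t = node.length if node.length is not None else 0.0
        for k in range(len(probs)):
            sel = classes == k
            if not sel.any():
                continue
            P = Pfuns[k](t)
            rows = np.cumsum(P, axis=1)
            rows /= rows[:, -1][:, None]
            u = rng.random(int(sel.sum()))
            par = parent_state[sel]
            child[sel] = np.array([
                int(np.searchsorted(rows[s], x)) for s, x in zip(par, u)
            ])
        states[id(node)] = child

    seqs = {
        leaf.name: "".join(CODONS[k] for k in states[id(leaf)])
        for leaf in tree.leaves
    }
    return CodonAlignment.from_strings(seqs), classes


# ---------------------------------------------------------------------------
# LP-like proteins
# ---------------------------------------------------------------------------

#: Mature-protein anchor positions of the synthetic reference (1-based):
#: Mn-binding triad E35/E39/D179, catalytic Trp 171, heme histidines 47/176.
ANCHOR_POSITIONS = {
    "mn1": (35, "E"),
    "mn2": (39, "E"),
    "mn3": (179, "D"),
    "trp": (171, "W"),
    "heme_distal": (47, "H"),
    "heme_proximal": (176, "H"),
}

_REFERENCE_LENGTH = 250
_REFERENCE_SEED = 20140325  # fixed: the reference is a constant of the module

# residues used to ablate an anchor, chosen not to satisfy any anchor rule
_ABLATION = {"mn1": "A", "mn2": "Q", "mn3": "N", "trp": "F"}


def reference_profile() -> str:
    """The fixed synthetic mature reference sequence with all anchors set."""
    rng = np.random.default_rng(_REFERENCE_SEED)
    seq = list(rng.choice(list(AA20), size=_REFERENCE_LENGTH))
    for pos, res in ANCHOR_POSITIONS.values():
        seq[pos - 1] = res
    return "".join(seq)


@dataclass
class LpTruth:
    """Truth table of a simulated LP protein set."""

    types: dict[str, str]
    cleavages: dict[str, int]


def sim_lp_proteins(
    n_per_type: Mapping[str, int] | int,
    seed: int = 0,
    sp_len_range: tuple[int, int] = (17, 26),
    mutation_rate: float = 0.1,
) -> tuple[list[ProteinRecord], LpTruth]:
    """LP-like proteins of requested types, with signal peptides.

    Sequences are mutated copies of the fixed reference at non-anchor
    positions; the Mn triad and/or catalytic Trp are present or ablated per
    type (heme histidines always kept); a random-length signal peptide
    starting with M is prepended and its cleavage recorded.  Classifying the
    mature sequences against the reference reproduces the truth table
    exactly.
    """
    if isinstance(n_per_type, int):
        n_per_type = {t: n_per_type for t in ("MnP", "LiP", "VP", "CII")}
    rng = np.random.default_rng(seed)
    ref = reference_profile()
    anchors = {pos for pos, _ in ANCHOR_POSITIONS.values()}
    aa = np.array(list(AA20))
    records: list[ProteinRecord] = []
    truth_types: dict[str, str] = {}
    truth_cleavage: dict[str, int] = {}
    counter = 0
    for lp_type in sorted(n_per_type):
        for k in range(n_per_type[lp_type]):
            counter += 1
            pid = f"syn_{lp_type}{k + 1:03d}"
            seq = list(ref)
            for i in range(len(seq)):
                if (i + 1) not in anchors and rng.random() < mutation_rate:
                    cur = seq[i]
                    choices = aa[aa != cur]
                    seq[i] = str(rng.choice(choices))
            if lp_type in ("CII", "LiP"):  # ablate Mn triad
                for key in ("mn1", "mn2", "mn3"):
                    pos, _ = ANCHOR_POSITIONS[key]
                    seq[pos - 1] = _ABLATION[key]
            if lp_type in ("CII", "MnP"):  # ablate catalytic Trp
                pos, _ = ANCHOR_POSITIONS["trp"]
                seq[pos - 1] = _ABLATION["trp"]
            sp_len = int(rng.integers(*sp_len_range))
            sp = "M" + "".join(rng.choice(aa, size=sp_len - 1))
            records.append(
                ProteinRecord(
                    id=pid,
                    residues=sp + "".join(seq),
                    species=f"Synthetica specie{counter % 4 + 1}",
                    order="Synthetales",
                    declared_type=lp_type,
                )
            )
            truth_types[pid] = lp_type
            truth_cleavage[pid] = sp_len
    return records, LpTruth(truth_types, truth_cleavage)


def reference_msa(records: Sequence[ProteinRecord],
                  truth: LpTruth) -> tuple[Msa, str]:
    """Gap-free alignment of mature simulated proteins plus the reference
    row (id ``REF``); exact because the simulator introduces no indels."""
    rows = {"REF": reference_profile()}
    for rec in records:
        rows[rec.id] = rec.residues[truth.cleavages[rec.id]:]
    return Msa(rows), "REF"


# ---------------------------------------------------------------------------
# Coding sequences and gene models
# ---------------------------------------------------------------------------

_AA_TO_CODONS: dict[str, list[str]] = {}
for _c, _a in zip(CODONS, CODON_AA):
    _AA_TO_CODONS.setdefault(_a, []).append(_c)


def reverse_translate(protein: str, seed: int = 0, stop: bool = True) -> str:
    """A random in-frame CDS translating to ``protein`` (plus a stop)."""
    rng = np.random.default_rng(seed)
    out = [str(rng.choice(_AA_TO_CODONS[a])) for a in protein]
    if stop:
        out.append("TAA")
    return "".join(out)


@dataclass
class IntronPlanEntry:
    """One planted homologous intron position.

    ``codon`` is the 1-based codon index the intron anchors to, ``phase``
    its frame offset, ``carriers`` the gene ids receiving it (None = all),
    ``jitter`` the maximum +/- codon shift applied per carrier."""

    codon: int
    phase: int
    carriers: Sequence[str] | None = None
    jitter: int = 0


@dataclass
class GeneModelTruth:
    clusters: dict[int, list[tuple[str, int]]]  # plan index -> (gene, codon)


def sim_gene_models(
    cds: Mapping[str, str],
    plan: Sequence[IntronPlanEntry],
    seed: int = 0,
    intron_length: tuple[int, int] = (50, 500),
    codon_offsets: Mapping[str, int] | None = None,
) -> tuple[dict[str, GeneModel], GeneModelTruth]:
    """Insert introns into coding sequences at planned positions.

    Intron sequences have canonical GT...AG ends and uniform random length
    (fungal-intron scale).  Jitter shifts each carrier's copy by up to the
    planned number of codons, emulating intron sliding.  ``codon_offsets``
    adds a per-gene shift to every planned position — pass each gene's
    signal-peptide length to plant positions homologous on the mature
    protein when the CDS includes the signal peptide.  Returns gene models
    (with genomic sequences attached) and the truth clusters (positions in
    plan coordinates, after jitter).
    """
    rng = np.random.default_rng(seed)
    codon_offsets = codon_offsets or {}
    truth = GeneModelTruth({k: [] for k in range(len(plan))})
    models: dict[str, GeneModel] = {}
    for gid in sorted(cds):
        seq = cds[gid].upper()
        n_codons = len(seq) // 3
        shift = codon_offsets.get(gid, 0)
        cuts: list[tuple[int, int]] = []  # (cds_offset, plan index)
        for pk, entry in enumerate(plan):
            if entry.carriers is not None and gid not in entry.carriers:
                continue
            if not (1 <= entry.codon + shift <= n_codons):
                raise ValueError(
                    f"plan entry {pk}: codon {entry.codon} (+{shift}) beyond "
                    f"CDS of {gid!r} ({n_codons} codons)"
                )
            codon = entry.codon
            if entry.jitter:
                codon += int(rng.integers(-entry.jitter, entry.jitter + 1))
            placed = min(max(codon + shift, 2), n_codons - 1)
            if entry.phase == 0:
                offset = 3 * (placed - 1)
            else:
                offset = 3 * (placed - 1) + entry.phase
            if offset < 1 or offset >= len(seq):
                raise ValueError(f"plan entry {pk}: offset {offset} out of CDS")
            cuts.append((offset, pk))
            truth.clusters[pk].append((gid, placed - shift))
        cuts.sort()
        if len({o for o, _ in cuts}) != len(cuts):
            raise ValueError(f"{gid!r}: two planned introns collide")
        genomic_parts: list[str] = []
        exons: list[tuple[int, int]] = []
        prev = 0
        gpos = 0
        for offset, _pk in cuts:
            exon = seq[prev:offset]
            exons.append((gpos, gpos + len(exon)))
            genomic_parts.append(exon)
            gpos += len(exon)
            ilen = int(rng.integers(intron_length[0], intron_length[1] + 1))
            inner = "".join(rng.choice(list("ACGT"), size=max(ilen - 4, 1)))
            intron = "GT" + inner + "AG"
            genomic_parts.append(intron)
            gpos += len(intron)
            prev = offset
        exon = seq[prev:]
        exons.append((gpos, gpos + len(exon)))
        genomic_parts.append(exon)
        models[gid] = GeneModel(
            id=gid, exons=exons, genomic="".join(genomic_parts)
        )
    return models, truth
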