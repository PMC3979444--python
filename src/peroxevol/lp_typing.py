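"""Key-residue typing of ligninolytic peroxidases on a reference alignment.

Class-II peroxidase types are defined by two catalytic features: the
Mn(II)-binding acidic triad (E35, E39, D179 in mature-MnP1 numbering of
*Phanerochaete chrysosporium*) and the surface tryptophan used to oxidize
high-redox-potential aromatics (W171 of mature LiPA).  A sequence with the
triad only is an MnP, with the tryptophan only a LiP, with both a VP, and
with neither a CII ("other class-II peroxidase").  Anchors are located on
reference rows of the alignment and read off every other row at the same
columns; a retained pair of heme-ligand histidines (distal and proximal) is
required for a sequence to enter the analysis at all.

Numbering is on the MATURE protein (signal peptide stripped); configs using
full-length numbering must offset positions by the signal-peptide length.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .phylo import GAP, Msa

# Acidic residues admitted at triad positions in "conservative" mode; natural
# Mn sites occasionally swap E and D.
_ACIDIC = {"E", "D"}


class TypingError(ValueError):
    pass


@dataclass(frozen=True)
class AnchorSite:
    """One reference-anchored position: row id, 1-based mature position,
    expected residue."""

    reference_id: str
    position: int
    expected: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise TypingError(f"anchor position must be >= 1: {self.position}")


@dataclass(frozen=True)
class ResidueAnchors:
    """The four catalytic anchors plus the heme-ligand histidines.

    Defaults follow mature-protein numbering of the two *P. chrysosporium*
    references: the Mn-binding triad on an MnP1-like row and the catalytic
    tryptophan on a LiPA-like row.  Heme histidine positions are not fixed by
    convention and must match the chosen reference."""

    mn_site: tuple[AnchorSite, AnchorSite, AnchorSite]
    trp_site: AnchorSite
    heme_site: tuple[AnchorSite, AnchorSite]

    @classmethod
    def default(
        cls,
        mn_reference: str,
        trp_reference: str | None = None,
        heme_positions: tuple[int, int] = (47, 176),
    ) -> "ResidueAnchors":
        trp_reference = trp_reference or mn_reference
        return cls(
            mn_site=(
                AnchorSite(mn_reference, 35, "E"),
                AnchorSite(mn_reference, 39, "E"),
                AnchorSite(mn_reference, 179, "D"),
            ),
            trp_site=AnchorSite(trp_reference, 171, "W"),
            heme_site=(
                AnchorSite(mn_reference, heme_positions[0], "H"),
                AnchorSite(mn_reference, heme_positions[1], "H"),
            ),
        )

    def all_sites(self) -> list[AnchorSite]:
        return [*self.mn_site, self.trp_site, *self.heme_site]


@dataclass
class TypeCall:
    """Classification of one sequence from its anchor-column residues."""

    id: str
    has_mn_site: bool
    has_trp: bool
    call: str
    anchor_columns: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        expect = {
            (True, True): "VP",
            (True, False): "MnP",
            (False, True): "LiP",
            (False, False): "CII",
        }[(self.has_mn_site, self.has_trp)]
        if self.call != expect:
            raise TypingError(
                f"{self.id}: call {self.call!r} inconsistent with flags"
            )


def map_reference_positions(
    msa: Msa, reference_id: str, positions: Sequence[int]
) -> list[int]:
    """Map 1-based ungapped positions of a reference row to 1-based columns.

    The k-th ungapped residue of the reference row sits in the returned
    column c(k); the mapping is strictly increasing.
    """
    if reference_id not in msa.rows:
        raise TypingError(f"reference {reference_id!r} not in alignment")
    cols = msa.ungapped_to_column(reference_id)
    out = []
    for pos in positions:
        if not (1 <= pos <= len(cols)):
            raise TypingError(
                f"position {pos} beyond reference length {len(cols)}"
            )
        out.append(cols[pos - 1])
    return out


def resolve_anchor_columns(msa: Msa, anchors: ResidueAnchors) -> dict[str, int]:
    """Resolve every anchor to its alignment column (1-based).

    Keys: mn1, mn2, mn3, trp, heme_distal, heme_proximal.
    """
    sites = {
        "mn1": anchors.mn_site[0],
        "mn2": anchors.mn_site[1],
        "mn3": anchors.mn_site[2],
        "trp": anchors.trp_site,
        "heme_distal": anchors.heme_site[0],
        "heme_proximal": anchors.heme_site[1],
    }
    out: dict[str, int] = {}
    for key, site in sites.items():
        (col,) = map_reference_positions(msa, site.reference_id, [site.position])
        ref_res = msa.rows[site.reference_id][col - 1]
        if ref_res != site.expected:
            raise TypingError(
                f"anchor {key}: reference row {site.reference_id!r} carries "
                f"{ref_res!r} at mature position {site.position}, expected "
                f"{site.expected!r}"
            )
        out[key] = col
    return out


def classify_lp(
    row_id: str,
    row: str,
    anchor_columns: Mapping[str, int],
    conservative: bool = False,
) -> TypeCall:
    """Classify one aligned row from its four catalytic anchor columns.

    Strict mode requires E, E, D at the triad columns and W at the
    tryptophan column; conservative mode admits E<->D interchange at the
    triad.  A gap at an anchor column counts as absence.  The call is a pure
    function of the four anchor-column residues.
    """
    def residue(key: str) -> str:
        return row[anchor_columns[key] - 1]

    triad = [residue("mn1"), residue("mn2"), residue("mn3")]
    if conservative:
        has_mn = all(r in _ACIDIC for r in triad)
    else:
        has_mn = triad[0] == "E" and triad[1] == "E" and triad[2] == "D"
    has_trp = residue("trp") == "W"
    call = {
        (True, True): "VP",
        (True, False): "MnP",
        (False, True): "LiP",
        (False, False): "CII",
    }[(has_mn, has_trp)]
    return TypeCall(row_id, has_mn, has_trp, call,
                    anchor_columns=dict(anchor_columns))


def classify_all(
    msa: Msa, anchors: ResidueAnchors, conservative: bool = False
) -> list[TypeCall]:
    cols = resolve_anchor_columns(msa, anchors)
    return [
        classify_lp(rid, row, cols, conservative=conservative)
        for rid, row in msa.rows.items()
    ]


def heme_filter(
    msa: Msa, anchors: ResidueAnchors
) -> tuple[list[str], list[tuple[str, str]]]:
    """Retain rows with histidine at both heme-ligand columns.

    Filtering looks ONLY at the heme columns: sequences lacking the
    substrate-oxidation residues (Mn triad, Trp) are kept so the CII class
    remains in the analysis.  Returns (kept ids, discarded (id, reason)).
    """
    cols = resolve_anchor_columns(msa, anchors)
    kept: list[str] = []
    discarded: list[tuple[str, str]] = []
    for rid, row in msa.rows.items():
        missing = [
            key for key in ("heme_distal", "heme_proximal")
            if row[cols[key] - 1] != "H"
        ]
        if missing:
            found = {k: row[cols[k] - 1] for k in missing}
            discarded.append(
                (rid, "no conserved heme-binding site: "
                 + ", ".join(f"{k}={v!r}" for k, v in found.items()))
            )
        else:
            kept.append(rid)
    return kept, discarded


def type_census(
    calls: Iterable[TypeCall], orders: Mapping[str, str]
) -> pd.DataFrame:
    """Contingency counts of calls per (type, taxonomic order).

    Returns a DataFrame indexed by type with one column per order plus a
    'total' column; marginals sum to the number of calls.
    """
    calls = list(calls)
    for c in calls:
        if c.id not in orders:
            raise TypingError(f"no taxonomic order for {c.id!r}")
    counter = Counter((c.call, orders[c.id]) for c in calls)
    types = sorted({c.call for c in calls})
    ords = sorted({orders[c.id] for c in calls})
    df = pd.DataFrame(0, index=types, columns=ords, dtype=int)
    for (t, o), n in counter.items():
        df.loc[t, o] = n
    df["total"] = df.sum(axis=1)
    return df
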