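"""Published selection-test summaries for the LP family, used as inputs.

The LP family analysis reports, for the whole 76-sequence set and for each
of its eight phylogenetic groups, the likelihood-ratio statistics of the
three nested site-model pairs together with the positive-class omega
estimates that were printed.  These summaries serve as input fixtures for
the decision-rule machinery: p-values are always recomputed from the
statistics via the chi-square tail, never transcribed.

A ``None`` statistic means the comparison was not pursued because no model
produced an omega above one; a ``None`` omega means no estimate was printed
for that model (an unprinted omega never ensures positive selection).  The
whole-family M7-vs-M8 statistic was not interpretable as printed; it is
replaced by a synthetic sub-critical stand-in (any value below the 2-df
0.05 threshold of 5.991 encodes the same published outcome: M8's omega of
2.38 exceeded one, but the LRT rejected the hypothesis).
"""

from __future__ import annotations

from dataclasses import dataclass

from .selection import SelectionVerdict, lrt_from_stat, positive_selection_decision


@dataclass(frozen=True)
class GroupSelectionSummary:
    """Published 2*delta-lnL statistics and positive-class omegas for one
    sequence set."""

    name: str
    stat_m0_m3: float | None
    stat_m1a_m2a: float | None
    stat_m7_m8: float | None
    omega_m3: float | None
    omega_m2a: float | None
    omega_m8: float | None
    expected_positive: bool

    def verdict(self) -> SelectionVerdict:
        """Run the positive-selection decision rule on this summary."""
        fits = {"M3": self.omega_m3, "M2a": self.omega_m2a, "M8": self.omega_m8}
        stats = {
            "M0 vs M3": self.stat_m0_m3,
            "M1a vs M2a": self.stat_m1a_m2a,
            "M7 vs M8": self.stat_m7_m8,
        }
        lrts = {
            pair: lrt_from_stat(pair, stat)
            for pair, stat in stats.items()
            if stat is not None
        }
        return positive_selection_decision(fits, lrts)


#: One entry per analyzed set: the whole family plus the eight groups.
LP_GROUP_SUMMARIES: tuple[GroupSelectionSummary, ...] = (
    GroupSelectionSummary("All sequences", None, None, 2.0,
                          None, None, 2.38, expected_positive=False),
    GroupSelectionSummary("LiP", None, None, None,
                          None, None, None, expected_positive=False),
    GroupSelectionSummary("VP", 6.663864, 1.475886, 2.073648,
                          None, None, None, expected_positive=False),
    GroupSelectionSummary("MnP I", 24.743772, 6.744184, 6.904412,
                          1.21, None, 1.49, expected_positive=True),
    GroupSelectionSummary("MnP II", None, None, None,
                          None, None, None, expected_positive=False),
    GroupSelectionSummary("MnP and VP", None, None, None,
                          None, None, None, expected_positive=False),
    GroupSelectionSummary("LiP and VP", None, None, None,
                          None, None, None, expected_positive=False),
    GroupSelectionSummary("MnP III", 220.201258, None, None,
                          1.56, None, None, expected_positive=True),
    GroupSelectionSummary("CII", 56.385656, 1.777202, 2.001702,
                          19.89, None, None, expected_positive=True),
)
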