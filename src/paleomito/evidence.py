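"""Mapping-based evidence for species identification.

Two of the three lines of evidence used to assign a species to an
ancient sample come from competitive per-reference mapping: how many
reads map to each candidate mitogenome, and how evenly they blanket it.
Evenness is the ratio of mean coverage (aligned bases / reference
length) to mean read depth over covered positions; algebraically this
equals the covered fraction of the reference (breadth), and both forms
are computed and kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mapping import AlignedRead
from .panel import PanelEntry, ReferencePanel

__all__ = [
    "CoverageSummary",
    "SpeciesCall",
    "depth_array",
    "coverage_summary",
    "normalized_counts",
    "call_species",
]


@dataclass
class CoverageSummary:
    """Per-reference mapping statistics after filtering and dedup.

    ``mean_coverage`` is S/L (aligned bases over reference length),
    ``mean_depth`` is S/B (aligned bases over covered positions), and
    ``evenness`` their ratio — identically B/L.
    """

    ref_id: str
    L: int
    n_mapped: int
    aligned_bases: int  # S
    covered_positions: int  # B
    mean_coverage: float  # C = S / L
    mean_depth: float  # D = S / B, 0 when nothing is covered
    evenness: float  # C / D, defined as 0 for zero coverage
    breadth_frac: float  # B / L
    depth: np.ndarray = field(repr=False, default=None)


def depth_array(alignments: list[AlignedRead], entry: PanelEntry) -> np.ndarray:
    """Per-position read depth with circular wrap-around."""
    L = entry.length
    diff = np.zeros(L + 1, dtype=np.int64)
    for a in alignments:
        if a.end <= L:
            diff[a.start] += 1
            diff[a.end] -= 1
        else:  # origin-spanning
            diff[a.start] += 1
            diff[L] -= 1
            diff[0] += 1
            diff[a.end - L] -= 1
    return np.cumsum(diff[:L])


def coverage_summary(alignments: list[AlignedRead], entry: PanelEntry) -> CoverageSummary:
    """Depth, breadth and evenness of a filtered, deduplicated alignment set."""
    depth = depth_array(alignments, entry)
    L = entry.length
    S = int(sum(a.aligned_len for a in alignments))
    B = int(np.count_nonzero(depth))
    C = S / L
    D = S / B if B else 0.0
    return CoverageSummary(
        ref_id=entry.ref_id,
        L=L,
        n_mapped=len(alignments),
        aligned_bases=S,
        covered_positions=B,
        mean_coverage=C,
        mean_depth=D,
        evenness=C / D if B else 0.0,
        breadth_frac=B / L,
        depth=depth,
    )


def normalized_counts(summaries: list[CoverageSummary]) -> pd.Series:
    """Mapped-read counts as percentages of the best reference.

    The reference with the most mapped reads gets exactly 100; all-zero
    inputs yield all-zero percentages with ``attrs['all_zero']`` set.
    """
    if not summaries:
        raise ValueError("need at least one coverage summary")
    counts = pd.Series({s.ref_id: s.n_mapped for s in summaries}, dtype=float)
    top = counts.max()
    if top == 0:
        out = counts * 0.0
        out.attrs["all_zero"] = True
        return out
    out = 100.0 * counts / top
    out.attrs["all_zero"] = False
    return out


@dataclass
class SpeciesCall:
    """Combined verdict over the available lines of evidence."""

    sample_id: str
    evidence: pd.DataFrame  # per-reference n_mapped, normalized_pct, evenness
    top_by_count: str | None
    top_by_evenness: str | None
    phylo_assignment: str | None
    verdict: str  # the called ref_id, or "ambiguous"
    notes: list[str]

    @property
    def is_concordant(self) -> bool:
        return self.verdict != "ambiguous"

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "top_by_count": self.top_by_count,
            "top_by_evenness": self.top_by_evenness,
            "phylo_assignment": self.phylo_assignment,
            "verdict": self.verdict,
            "notes": self.notes,
            "evidence": self.evidence.reset_index().to_dict(orient="records"),
        }


def call_species(
    sample_id: str,
    summaries: list[CoverageSummary],
    panel: ReferencePanel,
    phylo_assignment: str | None = None,
    count_margin: float = 0.1,
) -> SpeciesCall:
    """Combine read counts, evenness and (optionally) tree placement.

    Each line of evidence names one candidate reference or abstains:
    the count line abstains unless the top count exceeds the runner-up
    by ``count_margin`` (relative), and the evenness line abstains on an
    exact tie. The verdict is the named reference iff every available
    line names the same non-outgroup, non-contaminant reference;
    otherwise ``ambiguous``. A contaminant-control reference (e.g.
    human) can never be the verdict, but topping the raw counts earns a
    low-endogenous-content note.
    """
    if not summaries:
        raise ValueError("no coverage evidence supplied")
    notes: list[str] = []
    by_ref = {s.ref_id: s for s in summaries}
    eligible = [
        r for r in by_ref
        if r in panel and panel[r].role == "target"
    ]
    if not eligible:
        raise ValueError("no eligible (target) references among the summaries")

    # contaminant-control check on raw counts over all references
    all_sorted = sorted(by_ref.values(), key=lambda s: (-s.n_mapped, s.ref_id))
    overall_top = all_sorted[0]
    if overall_top.n_mapped > 0 and overall_top.ref_id in panel \
            and panel[overall_top.ref_id].is_contaminant_control:
        notes.append(
            f"low endogenous content: contaminant-control reference "
            f"{overall_top.ref_id!r} attracts the most reads"
        )

    elig_sorted = sorted(
        (by_ref[r] for r in eligible), key=lambda s: (-s.n_mapped, s.ref_id)
    )
    top_by_count: str | None = None
    if elig_sorted[0].n_mapped > 0:
        if len(elig_sorted) == 1 or elig_sorted[0].n_mapped >= (1.0 + count_margin) * max(
            elig_sorted[1].n_mapped, 1
        ):
            top_by_count = elig_sorted[0].ref_id
        else:
            notes.append("count line abstains: runner-up within margin")

    even_sorted = sorted(
        (by_ref[r] for r in eligible), key=lambda s: (-s.evenness, s.ref_id)
    )
    top_by_evenness: str | None = None
    if even_sorted[0].evenness > 0:
        if len(even_sorted) == 1 or even_sorted[0].evenness > even_sorted[1].evenness:
            top_by_evenness = even_sorted[0].ref_id
        else:
            notes.append("evenness line abstains: exact tie")

    lines = [top_by_count, top_by_evenness]
    if phylo_assignment is not None:
        lines.append(phylo_assignment)

    named = set(lines)
    if len(named) == 1 and None not in named:
        (candidate,) = named
        if candidate in eligible:
            verdict = candidate
        else:
            verdict = "ambiguous"
            notes.append(f"lines agree on ineligible reference {candidate!r}")
    else:
        verdict = "ambiguous"

    pct = normalized_counts(summaries)
    evidence = pd.DataFrame(
        {
            "n_mapped": {s.ref_id: s.n_mapped for s in summaries},
            "normalized_pct": pct,
            "evenness": {s.ref_id: s.evenness for s in summaries},
            "breadth_frac": {s.ref_id: s.breadth_frac for s in summaries},
        }
    )
    evidence.index.name = "ref_id"
    return SpeciesCall(
        sample_id=sample_id,
        evidence=evidence,
        top_by_count=top_by_count,
        top_by_evenness=top_by_evenness,
        phylo_assignment=phylo_assignment,
        verdict=verdict,
        notes=notes,
    )
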