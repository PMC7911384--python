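"""Ancient-DNA authenticity signals from alignments.

Post-mortem cytosine deamination shows up as C→T mismatches at 5′ read
ends and, on the complementary strand, G→A at 3′ ends, with frequency
decaying into the read. Profiling these two diagnostic mismatch classes
by distance from the read terminus (mapDamage-style) and inspecting the
fragment-length distribution are the standard desk checks that a
library behaves like degraded, authentic material rather than modern
contamination.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._dna import encode, revcomp_codes
from .mapping import AlignedRead
from .panel import PanelEntry

__all__ = [
    "DamageProfile",
    "LengthSummary",
    "damage_profile",
    "length_summary",
    "fit_damage_model",
]

_A, _C, _G, _T = 0, 1, 2, 3


@dataclass
class DamageProfile:
    """Terminal mismatch frequencies by offset from the read ends.

    ``pos5[i]`` is the C→T mismatch frequency at 5′ offset ``i`` (the
    fraction of reads whose reference base there is C and whose read
    base is T); ``pos3`` mirrors this with G→A from the 3′ terminus.
    Frequencies are NaN where no observation exists.
    """

    pos5: np.ndarray
    pos3: np.ndarray
    n_obs5: np.ndarray
    n_obs3: np.ndarray
    w: int
    no_data: bool = False
    full: pd.DataFrame | None = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i in range(self.w):
            rows.append(("CT_5p", i, self.pos5[i], int(self.n_obs5[i])))
            rows.append(("GA_3p", i, self.pos3[i], int(self.n_obs3[i])))
        return pd.DataFrame(rows, columns=["class", "offset", "freq", "n"])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _oriented(a: AlignedRead, ext: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(read codes, reference codes) in read orientation (5'→3')."""
    seq = encode(a.seq)
    ref = ext[a.start : a.end]
    if a.strand == "-":
        return revcomp_codes(seq), revcomp_codes(ref)
    return seq, ref


def damage_profile(
    alignments: list[AlignedRead],
    entry: PanelEntry,
    w: int = 15,
    full: bool = False,
) -> DamageProfile:
    """Count terminal C→T (5′) and G→A (3′) mismatch frequencies.

    Reverse-strand alignments are complement-flipped into read
    orientation before counting, so damage on either strand contributes
    to the same profile. With ``full=True`` a tidy table of all twelve
    mismatch classes per offset (both ends) is attached.
    """
    codes = encode(entry.sequence)
    ext = np.concatenate([codes, codes]) if entry.circular else codes

    num5 = np.zeros(w, dtype=np.int64)
    den5 = np.zeros(w, dtype=np.int64)
    num3 = np.zeros(w, dtype=np.int64)
    den3 = np.zeros(w, dtype=np.int64)
    full_counts = np.zeros((2, w, 4, 4), dtype=np.int64) if full else None

    for a in alignments:
        rb, ref = _oriented(a, ext)
        n = rb.size
        m = min(w, n)
        r5, b5 = ref[:m], rb[:m]
        isc = r5 == _C
        den5[:m] += isc
        num5[:m] += isc & (b5 == _T)
        r3, b3 = ref[n - m :][::-1], rb[n - m :][::-1]
        isg = r3 == _G
        den3[:m] += isg
        num3[:m] += isg & (b3 == _A)
        if full:
            for i in range(m):
                if r5[i] < 4 and b5[i] < 4:
                    full_counts[0, i, r5[i], b5[i]] += 1
                if r3[i] < 4 and b3[i] < 4:
                    full_counts[1, i, r3[i], b3[i]] += 1

    with np.errstate(invalid="ignore", divide="ignore"):
        pos5 = np.where(den5 > 0, num5 / np.maximum(den5, 1), np.nan)
        pos3 = np.where(den3 > 0, num3 / np.maximum(den3, 1), np.nan)

    full_df = None
    if full:
        bases = "ACGT"
        rows = []
        for e, end in enumerate(("5p", "3p")):
            for i in range(w):
                for r in range(4):
                    den = full_counts[e, i, r].sum()
                    for b in range(4):
                        if r == b:
                            continue
                        rows.append(
                            (end, i, f"{bases[r]}>{bases[b]}",
                             full_counts[e, i, r, b] / den if den else np.nan,
                             int(den))
                        )
        full_df = pd.DataFrame(rows, columns=["end", "offset", "class", "freq", "n"])

    return DamageProfile(
        pos5=pos5,
        pos3=pos3,
        n_obs5=den5,
        n_obs3=den3,
        w=w,
        no_data=not alignments,
        full=full_df,
    )


@dataclass
class LengthSummary:
    n: int
    mean: float
    sd: float
    histogram: dict[int, int]
    no_data: bool = False


def length_summary(alignments: list[AlignedRead]) -> LengthSummary:
    """Descriptive statistics over aligned read lengths."""
    if not alignments:
        return LengthSummary(n=0, mean=float("nan"), sd=float("nan"),
                             histogram={}, no_data=True)
    lens = np.array([a.aligned_len for a in alignments])
    vals, cnts = np.unique(lens, return_counts=True)
    return LengthSummary(
        n=lens.size,
        mean=float(lens.mean()),
        sd=float(lens.std(ddof=1)) if lens.size > 1 else 0.0,
        histogram={int(v): int(c) for v, c in zip(vals, cnts)},
    )


def fit_damage_model(profile: DamageProfile, n_offsets: int = 6) -> tuple[float, float]:
    """Recover (d5, decay_r) from a 5′ profile under the geometric model.

    Fits log f(i) = log d5 + i log r by least squares over the first
    ``n_offsets`` offsets, weighting each point by the (approximate)
    inverse variance of its log-frequency, n_obs * f.
    """
    f = profile.pos5[:n_offsets]
    n = profile.n_obs5[:n_offsets]
    i = np.arange(n_offsets)
    ok = np.isfinite(f) & (f > 0) & (n > 0)
    if ok.sum() < 2:
        raise ValueError("not enough informative offsets to fit the damage model")
    w = np.sqrt(n[ok] * f[ok])
    coef = np.polyfit(i[ok], np.log(f[ok]), deg=1, w=w)
    r_hat = float(np.exp(coef[0]))
    d5_hat = float(np.exp(coef[1]))
    return d5_hat, r_hat
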