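"""Synthetic reference panels and ancient-style single-end reads.

The generator emulates the data a hybridisation-capture experiment on
degraded bone yields: short (≤75 bp) single-end fragments with a
right-skewed length distribution, cytosine deamination expressed as C→T
mismatches at the 5′ end and G→A at the 3′ end decaying geometrically
into the read, uniform sequencing error, PCR duplicates that are exact
coordinate copies, and a controllable fraction of contaminant reads
drawn from non-target references (e.g. a human sequence). Reference
panels are mitogenome-scale circular sequences evolved from a common
ancestor by substitutions only, so every downstream coordinate is exact
and the generator's own mutation log can serve as an oracle in tests.

Truth about each read (source reference, 0-based start on the source,
strand, duplicate and contaminant flags) is encoded losslessly in the
read identifier::

    sim|<serial>|<source_ref>|<start>|<strand>|<D or .>|<C or .>

with ``|`` reserved as the delimiter (forbidden in reference ids).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import integrate, stats

from ._dna import decode, encode, revcomp_codes
from .panel import PanelEntry, ReferencePanel

MAX_DIVERGENCE = 0.75  # substitution saturation under a 4-letter alphabet

__all__ = [
    "PanelSpec",
    "ReadSimParams",
    "TruthTag",
    "SimulatedPanel",
    "SimulatedReads",
    "generate_panel",
    "simulate_reads",
    "score_against_truth",
    "parse_read_id",
    "truncated_lognormal_mean",
]


# --------------------------------------------------------------------------
# panel generation
# --------------------------------------------------------------------------

@dataclass
class PanelSpec:
    """Parameters for a synthetic reference panel.

    ``pairwise_divergence`` is the target substitutions/site between any
    two references under a star topology: each reference is evolved
    independently from a common ancestor with half the pairwise target on
    its own branch. ``branch_overrides`` lets individual references sit on
    longer branches (a human-like contaminant control at ~25 % divergence,
    say) and ``roles`` assigns panel roles by reference id.
    """

    n_refs: int
    ref_length: int = 16_500
    pairwise_divergence: float = 0.08
    seed: int = 0
    ref_ids: list[str] | None = None
    roles: dict[str, str] = field(default_factory=dict)
    branch_overrides: dict[str, float] = field(default_factory=dict)
    cr_length: int | None = None

    def __post_init__(self) -> None:
        if self.n_refs < 1:
            raise ValueError("n_refs must be >= 1")
        if self.ref_length < 1:
            raise ValueError("ref_length must be positive")
        if not (0.0 <= self.pairwise_divergence < MAX_DIVERGENCE):
            raise ValueError(
                f"pairwise divergence must lie in [0, {MAX_DIVERGENCE}) "
                "(substitution saturation)"
            )
        for ref, d in self.branch_overrides.items():
            if not (0.0 <= d < MAX_DIVERGENCE):
                raise ValueError(f"branch divergence for {ref!r} out of [0, 0.75)")
        if self.ref_ids is not None and len(self.ref_ids) != self.n_refs:
            raise ValueError("ref_ids length must equal n_refs")


@dataclass
class SimulatedPanel:
    """A generated panel together with its mutation log.

    ``variant_sites[ref_id]`` holds the 0-based positions where that
    reference differs from the common ancestor — the exact record of the
    substitutions the generator applied, usable as an oracle for
    alignment and identity statistics.
    """

    panel: ReferencePanel
    ancestor: str
    variant_sites: dict[str, np.ndarray]

    def realized_divergence(self, ref_a: str, ref_b: str) -> float:
        """Fraction of sites at which two references differ, from the log."""
        a = encode(self.panel[ref_a].sequence)
        b = encode(self.panel[ref_b].sequence)
        return float(np.mean(a != b))


def generate_panel(spec: PanelSpec) -> SimulatedPanel:
    """Evolve ``n_refs`` circular sequences from a random common ancestor.

    Substitution-only evolution: every sequence has exactly
    ``spec.ref_length`` bases and panel coordinates are shared. Each
    reference's branch mutates sites independently with probability
    ``pairwise_divergence / 2`` (or its ``branch_overrides`` value),
    drawing a uniformly random different base, so the realized pairwise
    divergence matches the target up to coincident hits.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.ref_length
    ancestor = rng.integers(0, 4, size=L).astype(np.uint8)

    ids = spec.ref_ids or [f"ref{i + 1:02d}" for i in range(spec.n_refs)]
    cr_len = spec.cr_length if spec.cr_length is not None else min(1_100, max(1, L // 15))
    cr_interval = (L - cr_len + 1, L)  # 1-based inclusive, at the "end" of the circle

    entries: list[PanelEntry] = []
    variant_sites: dict[str, np.ndarray] = {}
    for ref_id in ids:
        if "|" in ref_id:
            raise ValueError("'|' is reserved for truth tags and cannot appear in ref ids")
        branch = spec.branch_overrides.get(ref_id, spec.pairwise_divergence / 2.0)
        seq = ancestor.copy()
        hit = np.flatnonzero(rng.random(L) < branch)
        # substitute with a uniformly random *different* base
        seq[hit] = (seq[hit] + rng.integers(1, 4, size=hit.size).astype(np.uint8)) % 4
        entries.append(
            PanelEntry(
                ref_id=ref_id,
                sequence=decode(seq),
                circular=True,
                cr_interval=cr_interval,
                role=spec.roles.get(ref_id, "target"),
            )
        )
        variant_sites[ref_id] = hit

    return SimulatedPanel(
        panel=ReferencePanel(entries),
        ancestor=decode(ancestor),
        variant_sites=variant_sites,
    )


# --------------------------------------------------------------------------
# read simulation
# --------------------------------------------------------------------------

@dataclass
class ReadSimParams:
    """Knobs of the ancient-read model.

    Fragment lengths are lognormal with the given *distribution* mean and
    sd (in bases), truncated by rejection to [min_len, max_len] and
    rounded to integers. ``d5`` / ``d3`` are the deamination probabilities
    at the terminal position (C→T at the 5′ end, G→A at the 3′ end);
    the per-offset probability decays geometrically as ``d * decay_r**i``.
    Damage is applied before sequencing error. ``dup_rate`` is the
    fraction of emitted reads that are exact coordinate copies of another
    read (PCR duplicates); ``contam_fraction`` is the fraction drawn from
    the panel's contaminant-control references.
    """

    n_reads: int
    frag_len_mean: float = 55.0
    frag_len_sd: float = 15.0
    d5: float = 0.2
    d3: float = 0.2
    decay_r: float = 0.5
    seq_error: float = 0.005
    dup_rate: float = 0.05
    contam_fraction: float = 0.0
    min_len: int = 30
    max_len: int = 75
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("d5", "d3", "seq_error", "dup_rate", "contam_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a probability in [0, 1], got {v}")
        if not (0.0 < self.decay_r <= 1.0):
            raise ValueError("decay_r must lie in (0, 1]")
        if self.min_len < 1 or self.max_len < self.min_len:
            raise ValueError("need 1 <= min_len <= max_len")
        if self.n_reads < 0:
            raise ValueError("n_reads must be non-negative")


@dataclass(frozen=True)
class TruthTag:
    """Per-read provenance, losslessly encoded in the read identifier."""

    serial: int
    source_ref: str
    start: int  # 0-based on the source reference
    strand: str  # '+' or '-'
    is_duplicate: bool
    is_contaminant: bool

    def to_read_id(self) -> str:
        return "|".join(
            [
                "sim",
                f"{self.serial:06d}",
                self.source_ref,
                str(self.start),
                self.strand,
                "D" if self.is_duplicate else ".",
                "C" if self.is_contaminant else ".",
            ]
        )


def parse_read_id(read_id: str) -> TruthTag:
    """Recover the :class:`TruthTag` encoded in a simulated read id."""
    parts = read_id.split("|")
    if len(parts) != 7 or parts[0] != "sim":
        raise ValueError(f"not a simulated read id: {read_id!r}")
    return TruthTag(
        serial=int(parts[1]),
        source_ref=parts[2],
        start=int(parts[3]),
        strand=parts[4],
        is_duplicate=parts[5] == "D",
        is_contaminant=parts[6] == "C",
    )


@dataclass
class SimulatedReads:
    """Simulated reads, their truth table and the generator's damage log.

    ``truth`` has one row per read (read_id, source_ref, start, strand,
    length, is_duplicate, is_contaminant). ``damage_log`` records every
    deamination event the generator applied: (read_id, offset5, offset3,
    kind) where one of the offsets is -1 and kind is ``CT`` or ``GA``.
    """

    reads: list[tuple[str, str]]  # (read_id, sequence)
    truth: pd.DataFrame
    damage_log: pd.DataFrame

    def __len__(self) -> int:
        return len(self.reads)

    def write_fastq(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for read_id, seq in self.reads:
                fh.write(f"@{read_id}\n{seq}\n+\n{'F' * len(seq)}\n")

    def write_truth(self, path: str | Path) -> None:
        self.truth.to_csv(path, sep="\t", index=False)


def _sample_lengths(rng, params: ReadSimParams, n: int) -> np.ndarray:
    """Truncated, integer-rounded lognormal fragment lengths."""
    mean, sd = params.frag_len_mean, params.frag_len_sd
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    sigma = math.sqrt(sigma2)
    out = np.empty(n, dtype=np.int64)
    filled = 0
    while filled < n:
        draw = rng.lognormal(mu, sigma, size=max(2 * (n - filled), 64))
        draw = np.rint(draw).astype(np.int64)
        ok = draw[(draw >= params.min_len) & (draw <= params.max_len)]
        take = min(ok.size, n - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
    return out


def truncated_lognormal_mean(params: ReadSimParams) -> float:
    """Expected fragment length under the truncated lognormal model.

    Computed by numerical integration of the continuous truncated
    density (integer rounding shifts the mean by < 0.05 base for the
    defaults and is ignored here).
    """
    mean, sd = params.frag_len_mean, params.frag_len_sd
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    sigma = math.sqrt(sigma2)
    dist = stats.lognorm(s=sigma, scale=math.exp(mu))
    a, b = params.min_len - 0.5, params.max_len + 0.5
    mass = dist.cdf(b) - dist.cdf(a)
    num, _ = integrate.quad(lambda x: x * dist.pdf(x), a, b)
    return num / mass


def _source_fractions(
    panel: ReferencePanel,
    source_mix: dict[str, float] | None,
    contam_fraction: float,
) -> dict[str, float]:
    if source_mix is None:
        tgt = [e.ref_id for e in panel.targets()]
        if not tgt:
            raise ValueError("panel has no target references to draw from")
        source_mix = {r: 1.0 / len(tgt) for r in tgt}
    total = sum(source_mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"source fractions must sum to 1 (got {total})")
    for r in source_mix:
        if r not in panel:
            raise KeyError(f"source reference {r!r} not in panel")
    if contam_fraction > 0:
        contam = [e.ref_id for e in panel if e.is_contaminant_control]
        if not contam:
            raise ValueError("contam_fraction > 0 but no contaminant_control reference in panel")
        mix = {r: f * (1.0 - contam_fraction) for r, f in source_mix.items()}
        for r in contam:
            mix[r] = mix.get(r, 0.0) + contam_fraction / len(contam)
        return mix
    return dict(source_mix)


def simulate_reads(
    panel: ReferencePanel,
    params: ReadSimParams,
    source_mix: dict[str, float] | None = None,
) -> SimulatedReads:
    """Draw ancient-style single-end reads from a panel.

    Fragments start uniformly on the circular source (origin-spanning
    fragments wrap), each strand with probability 1/2. Deamination is
    applied to the fragment in read orientation — at 5′ offset *i* a C
    becomes T with probability ``d5 * decay_r**i``, mirrored with G→A
    from the 3′ end — then uniform sequencing error replaces bases with
    a random different base. Duplicates copy a parent read's coordinates
    and damaged sequence and receive independent sequencing error.
    """
    if len(panel) == 0:
        raise ValueError("empty reference panel")
    mix = _source_fractions(panel, source_mix, params.contam_fraction)
    rng = np.random.default_rng(params.seed)

    n_total = params.n_reads
    if n_total == 0:
        empty_truth = pd.DataFrame(
            columns=["read_id", "source_ref", "start", "strand", "length",
                     "is_duplicate", "is_contaminant"]
        )
        empty_dmg = pd.DataFrame(columns=["read_id", "offset5", "offset3", "kind"])
        return SimulatedReads([], empty_truth, empty_dmg)

    n_dup = int(round(params.dup_rate * n_total))
    n_orig = max(n_total - n_dup, 1)
    n_dup = n_total - n_orig

    ref_ids = sorted(mix)
    probs = np.array([mix[r] for r in ref_ids])
    probs = probs / probs.sum()
    # doubled arrays let origin-spanning fragments be plain slices
    doubled = {
        r: np.concatenate([encode(panel[r].sequence), encode(panel[r].sequence)[: params.max_len]])
        for r in ref_ids
    }
    lengths = _sample_lengths(rng, params, n_orig)
    src_idx = rng.choice(len(ref_ids), size=n_orig, p=probs)
    strands = np.where(rng.random(n_orig) < 0.5, "+", "-")

    reads: list[tuple[str, str]] = []
    truth_rows: list[tuple] = []
    dmg_rows: list[tuple] = []
    originals: list[tuple[np.ndarray, TruthTag]] = []  # damaged, pre-error codes

    for i in range(n_orig):
        ref = ref_ids[src_idx[i]]
        L = panel[ref].length
        flen = int(lengths[i])
        if flen > L:
            flen = L
        start = int(rng.integers(0, L))
        frag = doubled[ref][start : start + flen].copy()
        strand = str(strands[i])
        if strand == "-":
            frag = revcomp_codes(frag)

        tag = TruthTag(
            serial=i,
            source_ref=ref,
            start=start,
            strand=strand,
            is_duplicate=False,
            is_contaminant=panel[ref].is_contaminant_control,
        )
        rid = tag.to_read_id()

        # deamination in read orientation, before sequencing error
        offs = np.arange(flen)
        p5 = params.d5 * params.decay_r ** offs
        hit5 = np.flatnonzero((frag == 1) & (rng.random(flen) < p5))
        p3 = params.d3 * params.decay_r ** offs[::-1]
        hit3 = np.flatnonzero((frag == 2) & (rng.random(flen) < p3))
        frag[hit5] = 3  # C -> T
        frag[hit3] = 0  # G -> A
        for o in hit5:
            dmg_rows.append((rid, int(o), -1, "CT"))
        for o in hit3:
            dmg_rows.append((rid, -1, int(flen - 1 - o), "GA"))

        originals.append((frag.copy(), tag))

        err = np.flatnonzero(rng.random(flen) < params.seq_error)
        if err.size:
            frag = frag.copy()
            frag[err] = (frag[err] + rng.integers(1, 4, size=err.size).astype(np.uint8)) % 4

        reads.append((rid, decode(frag)))
        truth_rows.append((rid, ref, start, strand, flen, False, tag.is_contaminant))

    # PCR duplicates: exact coordinate copies sharing the parent's damage,
    # with independent sequencing error
    if n_dup:
        parents = rng.integers(0, n_orig, size=n_dup)
        for j, pi in enumerate(parents):
            frag, ptag = originals[int(pi)]
            frag = frag.copy()
            flen = frag.size
            err = np.flatnonzero(rng.random(flen) < params.seq_error)
            if err.size:
                frag[err] = (frag[err] + rng.integers(1, 4, size=err.size).astype(np.uint8)) % 4
            tag = TruthTag(
                serial=n_orig + j,
                source_ref=ptag.source_ref,
                start=ptag.start,
                strand=ptag.strand,
                is_duplicate=True,
                is_contaminant=ptag.is_contaminant,
            )
            rid = tag.to_read_id()
            reads.append((rid, decode(frag)))
            truth_rows.append(
                (rid, tag.source_ref, tag.start, tag.strand, flen, True, tag.is_contaminant)
            )

    truth = pd.DataFrame(
        truth_rows,
        columns=["read_id", "source_ref", "start", "strand", "length",
                 "is_duplicate", "is_contaminant"],
    )
    damage_log = pd.DataFrame(dmg_rows, columns=["read_id", "offset5", "offset3", "kind"])
    return SimulatedReads(reads, truth, damage_log)


# --------------------------------------------------------------------------
# scoring
# --------------------------------------------------------------------------

def score_against_truth(
    calls: dict[str, str | None],
    truth: dict[str, str],
) -> pd.DataFrame:
    """Score top-ranked species calls against known sources.

    ``calls`` maps replicate/sample id to the called reference (None for
    no call); ``truth`` maps the same ids to the true source reference.
    Returns a confusion table with an ``accuracy`` attribute in
    ``DataFrame.attrs``.
    """
    if not calls:
        raise ValueError("no calls to score")
    if set(calls) != set(truth):
        raise ValueError("call ids do not match truth ids")
    rows = [(sid, truth[sid], calls[sid]) for sid in sorted(calls)]
    df = pd.DataFrame(rows, columns=["sample_id", "true_ref", "called_ref"])
    df["correct"] = df["true_ref"] == df["called_ref"]
    confusion = (
        df.groupby(["true_ref", "called_ref"], dropna=False).size().rename("n").reset_index()
    )
    confusion.attrs["accuracy"] = float(df["correct"].mean())
    confusion.attrs["n"] = len(df)
    return confusion
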