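"""Reference panels: named circular mitogenomes plus per-reference annotations.

A panel bundles the candidate reference sequences that reads are mapped
against — typically several canid mitogenomes, a phylogenetic outgroup
(e.g. gray fox) and a human sequence kept as a contaminant control. Each
entry carries its control-region interval (1-based inclusive) so the
rapidly evolving segment can be excised before diversity analyses.

On disk a panel is a multi-FASTA plus a tab-separated annotation table
with columns ``ref_id  cr_start  cr_end  role`` where role is one of
``target``, ``outgroup``, ``contaminant_control``. Missing annotation rows
default to ``target`` with no control-region interval.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ROLES = ("target", "outgroup", "contaminant_control")


@dataclass
class PanelEntry:
    """One reference sequence and its annotations."""

    ref_id: str
    sequence: str
    circular: bool = True
    cr_interval: tuple[int, int] | None = None  # 1-based inclusive
    role: str = "target"

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"reference {self.ref_id!r} has an empty sequence")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(
                f"reference {self.ref_id!r} contains non-ACGTN characters: {sorted(bad)}"
            )
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r} (expected one of {ROLES})")
        if self.cr_interval is not None:
            a, b = self.cr_interval
            if not (1 <= a <= b <= len(self.sequence)):
                raise ValueError(
                    f"control-region interval {self.cr_interval} invalid for "
                    f"{self.ref_id!r} of length {len(self.sequence)}"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def is_outgroup(self) -> bool:
        return self.role == "outgroup"

    @property
    def is_contaminant_control(self) -> bool:
        return self.role == "contaminant_control"


@dataclass
class ReferencePanel:
    """An ordered collection of :class:`PanelEntry` with unique ids."""

    entries: list[PanelEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [e.ref_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate ref_ids in panel")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, ref_id: str) -> PanelEntry:
        for e in self.entries:
            if e.ref_id == ref_id:
                return e
        raise KeyError(ref_id)

    def __contains__(self, ref_id: str) -> bool:
        return any(e.ref_id == ref_id for e in self.entries)

    @property
    def ref_ids(self) -> list[str]:
        return [e.ref_id for e in self.entries]

    def targets(self) -> list[PanelEntry]:
        return [e for e in self.entries if e.role == "target"]

    # ------------------------------------------------------------------ I/O

    def write(self, fasta_path: str | Path, annotations_path: str | Path | None = None) -> None:
        records = [
            SeqRecord(Seq(e.sequence), id=e.ref_id, description="")
            for e in self.entries
        ]
        SeqIO.write(records, str(fasta_path), "fasta")
        if annotations_path is not None:
            with open(annotations_path, "w", newline="") as fh:
                w = csv.writer(fh, delimiter="\t", lineterminator="\n")
                w.writerow(["ref_id", "cr_start", "cr_end", "role"])
                for e in self.entries:
                    a, b = e.cr_interval if e.cr_interval else ("", "")
                    w.writerow([e.ref_id, a, b, e.role])

    @classmethod
    def read(
        cls,
        fasta_path: str | Path,
        annotations_path: str | Path | None = None,
        circular: bool = True,
    ) -> "ReferencePanel":
        ann: dict[str, dict] = {}
        if annotations_path is not None:
            with open(annotations_path) as fh:
                for row in csv.DictReader(fh, delimiter="\t"):
                    cr = None
                    if row.get("cr_start") and row.get("cr_end"):
                        cr = (int(row["cr_start"]), int(row["cr_end"]))
                    ann[row["ref_id"]] = {
                        "cr_interval": cr,
                        "role": row.get("role") or "target",
                    }
        entries = []
        for rec in SeqIO.parse(str(fasta_path), "fasta"):
            a = ann.get(rec.id, {})
            entries.append(
                PanelEntry(
                    ref_id=rec.id,
                    sequence=str(rec.seq),
                    circular=circular,
                    cr_interval=a.get("cr_interval"),
                    role=a.get("role", "target"),
                )
            )
        return cls(entries)
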