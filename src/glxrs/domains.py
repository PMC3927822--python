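"""Domain splitting, HIGH-motif scanning and Yqey-appendix detection.

GluRS and GlnRS are two-domain class-I synthetases: an N-terminal catalytic
(Rossmann-fold) domain and a C-terminal anticodon-binding domain.  The
domain boundary is projected from a reference row of the multiple alignment
(boundary residue 322 of the Thermus thermophilus enzyme by default, giving
1-322 / 323-468 domains for a 468-residue reference).

The class-I 'HIGH' signature is matched as the 4-mer pattern H[IVL]G[GNSTLM]
near the start of the catalytic domain.  Some GlnRS carry an extra ~140
residue Yqey paralog appended after the canonical C-terminus; it is detected
by projecting a Yqey-containing and a Yqey-lacking reference onto the
alignment and measuring the query's extension past the projected core end.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

HIGH_MOTIF_RE = re.compile(r"H[IVL]G[GNSTLM]")
PHI = "ϕ"  # the phi placeholder in the collapsed motif rendering


@dataclass
class AlignedSet:
    """An aligned protein set: equal-length gapped rows over AA + ``'-'``."""

    ids: list[str]
    rows: list[str]
    reference_id: str | None = None

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids in alignment")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"rows are not equal length: {sorted(lengths)}")
        if self.reference_id is not None:
            ref = self.row(self.reference_id)
            if not ref.strip("-"):
                raise ValueError("reference row has no non-gap characters")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, seq_id: str) -> str:
        try:
            return self.rows[self.ids.index(seq_id)]
        except ValueError:
            raise KeyError(f"sequence {seq_id!r} not in alignment") from None

    def column_of_residue(self, seq_id: str, residue: int) -> int:
        """1-based alignment column holding 1-based ``residue`` of ``seq_id``."""
        if residue < 1:
            raise ValueError("residue numbers are 1-based")
        seen = 0
        for col, ch in enumerate(self.row(seq_id), start=1):
            if ch != "-":
                seen += 1
                if seen == residue:
                    return col
        raise ValueError(
            f"sequence {seq_id!r} has only {seen} residues; residue {residue} "
            "does not exist"
        )

    @classmethod
    def from_fasta(cls, path: str | Path, reference_id: str | None = None) -> "AlignedSet":
        from Bio import SeqIO

        ids, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id)
            rows.append(str(rec.seq).upper())
        return cls(ids=ids, rows=rows, reference_id=reference_id)

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for sid, row in zip(self.ids, self.rows):
                fh.write(f">{sid}\n{row}\n")


@dataclass(frozen=True)
class DomainSplit:
    id: str
    n_domain: str
    c_domain: str
    split_column: int
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class MotifCall:
    id: str
    status: str  # "found" | "absent"
    variant: str | None = None
    position: int | None = None  # 1-based offset in the N-domain
    all_hits: tuple[tuple[int, str], ...] = ()


@dataclass(frozen=True)
class YqeyCall:
    id: str
    present: bool
    extension_length: int
    identity_to_ref: float


def split_domains(aln: AlignedSet, boundary_residue: int = 322) -> list[DomainSplit]:
    """Split every row into N/C domains at the reference boundary residue.

    The split column is the alignment column holding reference residue
    ``boundary_residue``; for every row, non-gap characters in columns up to
    and including that column form the N domain and the remainder the C
    domain, so ``n + c`` always reconstructs the ungapped input.
    """
    if aln.reference_id is None:
        raise ValueError("split_domains requires an alignment reference_id")
    split_col = aln.column_of_residue(aln.reference_id, boundary_residue)
    out = []
    for sid, row in zip(aln.ids, aln.rows):
        n_dom = row[:split_col].replace("-", "")
        c_dom = row[split_col:].replace("-", "")
        flags = []
        if not n_dom:
            flags.append("empty_n_domain")
        if not c_dom:
            flags.append("empty_c_domain")
        out.append(DomainSplit(sid, n_dom, c_dom, split_col, tuple(flags)))
    return out


def find_high_motif(n_domain: str, window: int = 60, seq_id: str = "") -> MotifCall:
    """First HIGH-motif hit (pattern ``H[IVL]G[GNSTLM]``) in the window.

    Only matches that start within the first ``window`` residues of the
    catalytic domain are considered; the N-terminal-most hit wins and every
    windowed hit is retained in ``all_hits`` (1-based positions).
    """
    if not n_domain:
        raise ValueError("find_high_motif requires a non-empty sequence")
    region = n_domain[: window + 3]  # a hit may start at position `window`
    hits = tuple(
        (m.start() + 1, m.group())
        for m in HIGH_MOTIF_RE.finditer(region)
        if m.start() < window
    )
    if not hits:
        return MotifCall(id=seq_id, status="absent")
    pos, variant = hits[0]
    return MotifCall(id=seq_id, status="found", variant=variant, position=pos,
                     all_hits=hits)


def collapse_variant(variant: str) -> str:
    """Collapse the phi position: ``'HIGG' -> 'HϕGG'``."""
    if not HIGH_MOTIF_RE.fullmatch(variant):
        raise ValueError(f"{variant!r} is not a HIGH-motif variant")
    return f"H{PHI}G{variant[3]}"


def motif_census(
    calls: Iterable[MotifCall], groups: Mapping[str, str]
) -> pd.DataFrame:
    """Collapsed-variant x group count table; absent calls counted as 'absent'."""
    records = []
    for call in calls:
        if call.id not in groups:
            raise ValueError(f"no group label for sequence {call.id!r}")
        variant = collapse_variant(call.variant) if call.status == "found" else "absent"
        records.append({"variant": variant, "group": groups[call.id]})
    if not records:
        return pd.DataFrame()
    df = pd.DataFrame.from_records(records)
    return df.groupby(["variant", "group"]).size().unstack(fill_value=0)


def detect_yqey(
    query_id: str,
    aln: AlignedSet,
    yqey_ref: str,
    core_ref: str,
    core_end: int = 673,
    yqey_span: tuple[int, int] = (710, 852),
    min_extension: int = 60,
    min_identity: float = 0.25,
) -> YqeyCall:
    """Detect a Yqey paralog appended after the canonical GlnRS C-terminus.

    ``core_ref`` is a Yqey-lacking reference whose residue ``core_end``
    projects the canonical core end onto the alignment; ``yqey_ref`` is a
    Yqey-containing reference whose residues ``yqey_span`` delimit the
    appendix.  The appendix is called present when the query has at least
    ``min_extension`` residues beyond the projected core end and at least
    ``min_identity`` fractional identity to the reference over the appendix
    projection.
    """
    for ref in (yqey_ref, core_ref):
        if ref not in aln.ids:
            raise ValueError(f"reference {ref!r} absent from alignment")
    query_row = aln.row(query_id)
    core_end_col = aln.column_of_residue(core_ref, core_end)
    extension = sum(1 for ch in query_row[core_end_col:] if ch != "-")

    yqey_row = aln.row(yqey_ref)
    start_col = aln.column_of_residue(yqey_ref, yqey_span[0])
    end_col = aln.column_of_residue(yqey_ref, yqey_span[1])
    span_cols = range(start_col - 1, end_col)  # 0-based slice of columns
    n_ref = sum(1 for i in span_cols if yqey_row[i] != "-")
    matches = sum(
        1
        for i in span_cols
        if yqey_row[i] != "-" and query_row[i] == yqey_row[i]
    )
    identity = matches / n_ref if n_ref else 0.0
    return YqeyCall(
        id=query_id,
        present=extension >= min_extension and identity >= min_identity,
        extension_length=extension,
        identity_to_ref=identity,
    )


def motif_report(calls: Iterable[MotifCall], path: str | Path) -> pd.DataFrame:
    """Write per-sequence motif calls as TSV; returns the frame written."""
    df = pd.DataFrame(
        [
            {
                "id": c.id,
                "status": c.status,
                "variant": c.variant or "",
                "collapsed": collapse_variant(c.variant) if c.variant else "",
                "position": c.position if c.position is not None else "",
            }
            for c in calls
        ]
    )
    df.to_csv(path, sep="\t", index=False)
    return df
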