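"""tRNA(Gln) identity-element profiling on canonically numbered alignments.

tRNA positions follow the canonical (Sprinzl-style) numbering supplied as an
explicit position map per alignment; this module validates and consumes the
map, it never infers secondary structure.  Profiled elements:

* acceptor-stem determinants U1-A72, G2-C71, G3-C70 and D-stem G10;
* the anticodon (positions 34-36): UUG -> isotype Gln1, CUG -> Gln2;
* the anticodon-loop signature U32-U38 with A37 (``signature_3238``),
  characteristic of gamma-/beta-proteobacterial tRNA(Gln), versus e.g. the
  C32-A38/G37 combination of Thermus thermophilus.

``signature_3238`` is three-valued: a gap at 32/37/38 yields a no-call
(``None``), distinct from ``False``, and no-calls are excluded from
summaries with an explicit count.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

CANONICAL_POSITIONS = (1, 2, 3, 10, 32, 33, 34, 35, 36, 37, 38, 70, 71, 72)
ACCEPTOR_PAIRS = ((1, 72), (2, 71), (3, 70))
WC_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}

ISOTYPE_BY_ANTICODON = {"UUG": "Gln1", "CUG": "Gln2"}


@dataclass(frozen=True)
class TRNARecord:
    """An aligned tRNA sequence plus its canonical-position -> column map."""

    id: str
    genome_id: str
    seq: str  # aligned, over {A, C, G, U, -}
    position_map: Mapping[int, int]  # canonical position -> 1-based column

    def __post_init__(self) -> None:
        bad = set(self.seq) - set("ACGU-")
        if bad:
            raise ValueError(f"invalid tRNA characters {sorted(bad)} in {self.id!r}")
        cols = list(self.position_map.values())
        if len(set(cols)) != len(cols):
            raise ValueError(f"position map for {self.id!r} is not injective")
        out_of_range = [c for c in cols if not 1 <= c <= len(self.seq)]
        if out_of_range:
            raise ValueError(
                f"position map columns outside alignment for {self.id!r}: "
                f"{out_of_range}"
            )


@dataclass(frozen=True)
class IdentityProfile:
    id: str
    genome_id: str
    isotype: str  # "Gln1" | "Gln2" | "other"
    bases: Mapping[int, str | None]  # canonical position -> base, None if gapped
    acceptor_pairs: Mapping[str, tuple[str | None, str | None]]


def extract_profile(rec: TRNARecord) -> IdentityProfile:
    """Read the identity-element bases of one record (pure lookup)."""
    missing = [p for p in CANONICAL_POSITIONS if p not in rec.position_map]
    if missing:
        raise ValueError(
            f"record {rec.id!r} lacks canonical positions {missing} in its map"
        )
    bases: dict[int, str | None] = {}
    for pos in CANONICAL_POSITIONS:
        ch = rec.seq[rec.position_map[pos] - 1]
        bases[pos] = None if ch == "-" else ch
    anticodon = "".join(bases[p] or "-" for p in (34, 35, 36))
    isotype = ISOTYPE_BY_ANTICODON.get(anticodon, "other")
    pairs = {
        f"{a}:{b}": (bases[a], bases[b]) for a, b in ACCEPTOR_PAIRS
    }
    return IdentityProfile(
        id=rec.id, genome_id=rec.genome_id, isotype=isotype,
        bases=bases, acceptor_pairs=pairs,
    )


def signature_3238(profile: IdentityProfile) -> bool | None:
    """U32-U38 with A37, three-valued: gap at 32/37/38 yields a no-call."""
    b32, b37, b38 = (profile.bases.get(p) for p in (32, 37, 38))
    if b32 is None or b37 is None or b38 is None:
        return None
    return b32 == "U" and b38 == "U" and b37 == "A"


def conservation_summary(
    profiles: Iterable[IdentityProfile],
    grouping: Mapping[str, str],
) -> dict[str, pd.DataFrame]:
    """Per-group conservation of identity elements.

    Returns three frames keyed ``'positions'`` (modal base and frequency per
    canonical position per group), ``'pairs'`` (Watson-Crick match fraction
    per acceptor pair per group), and ``'signature'`` (signature_3238
    frequency per group with no-call counts reported, not counted).
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("conservation_summary requires at least one profile")
    pos_records, pair_records, sig_records = [], [], []
    by_group: dict[str, list[IdentityProfile]] = {}
    for prof in profiles:
        if prof.genome_id not in grouping:
            raise ValueError(f"no group for genome {prof.genome_id!r}")
        by_group.setdefault(grouping[prof.genome_id], []).append(prof)

    for group in sorted(by_group):
        members = by_group[group]
        for pos in CANONICAL_POSITIONS:
            observed = [p.bases[pos] for p in members if p.bases[pos] is not None]
            if observed:
                counts = pd.Series(observed).value_counts()
                modal, freq = counts.index[0], counts.iloc[0] / len(observed)
            else:
                modal, freq = None, float("nan")
            pos_records.append(
                {"group": group, "position": pos, "modal_base": modal,
                 "frequency": freq, "n": len(observed)}
            )
        for a, b in ACCEPTOR_PAIRS:
            called = [
                (p.bases[a], p.bases[b]) for p in members
                if p.bases[a] is not None and p.bases[b] is not None
            ]
            matches = sum(1 for pair in called if pair in WC_PAIRS)
            pair_records.append(
                {"group": group, "pair": f"{a}:{b}",
                 "wc_fraction": matches / len(called) if called else float("nan"),
                 "n": len(called)}
            )
        calls = [signature_3238(p) for p in members]
        called = [c for c in calls if c is not None]
        sig_records.append(
            {"group": group,
             "signature_fraction": (
                 sum(called) / len(called) if called else float("nan")
             ),
             "n_called": len(called),
             "n_no_call": len(calls) - len(called)}
        )
    return {
        "positions": pd.DataFrame.from_records(pos_records),
        "pairs": pd.DataFrame.from_records(pair_records),
        "signature": pd.DataFrame.from_records(sig_records),
    }


# ---------------------------------------------------------------------------
# File interfaces

def read_position_map(path: str | Path) -> dict[int, int]:
    """Position-map TSV with columns ``canonical_position`` and ``column``."""
    df = pd.read_csv(path, sep="\t")
    for col in ("canonical_position", "column"):
        if col not in df.columns:
            raise ValueError(f"position map TSV missing column {col!r}")
    return dict(zip(df["canonical_position"].astype(int), df["column"].astype(int)))


def write_position_map(position_map: Mapping[int, int], path: str | Path) -> None:
    pd.DataFrame(
        sorted(position_map.items()), columns=["canonical_position", "column"]
    ).to_csv(path, sep="\t", index=False)


def read_trna_fasta(
    path: str | Path, position_map: Mapping[int, int]
) -> list[TRNARecord]:
    """Aligned tRNA FASTA; record ids are ``genome_id`` or ``genome_id|tag``."""
    from Bio import SeqIO

    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        genome_id = rec.id.split("|")[0]
        records.append(
            TRNARecord(
                id=rec.id, genome_id=genome_id,
                seq=str(rec.seq).upper().replace("T", "U"),
                position_map=dict(position_map),
            )
        )
    return records


def profiles_to_frame(profiles: Iterable[IdentityProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row = {"id": p.id, "genome_id": p.genome_id, "isotype": p.isotype}
        row.update({f"pos{k}": v or "-" for k, v in p.bases.items()})
        sig = signature_3238(p)
        row["signature_3238"] = "no-call" if sig is None else str(sig).lower()
        rows.append(row)
    return pd.DataFrame.from_records(rows)
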