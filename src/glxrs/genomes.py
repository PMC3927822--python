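"""Genome co-occurrence classification for the Gln-tRNA(Gln) synthesis machinery.

Each bacterial genome is summarised by the copy number of glutamyl-tRNA
synthetase (gene ``gltX``), and the presence/absence of glutaminyl-tRNA
synthetase (``glnS``) and of the heterotrimeric amidotransferase gatCAB
(``gatA`` + ``gatB`` + ``gatC``).  Genomes fall into five legal
co-occurrence groups, written ``<copies|glnS|gatCAB>`` (e.g. ``1|-|+``),
and every GluRS copy receives a functional-type annotation:

* single copy, GlnRS absent, gatCAB present  -> non-discriminating (ND-GluRS)
* single copy, GlnRS present, gatCAB absent  -> discriminating, D(-)-GluRS
* single copy, GlnRS present, gatCAB present -> nominally discriminating, D(+)-GluRS
* two copies -> GluRS1 (canonical) and GluRS2 (tRNA(Gln)-specific or inactive)

Pseudogenes are consumed as input flags and count as absence everywhere.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import ClassVar, Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

GENE_VOCABULARY = frozenset({"gltX", "glnS", "gatA", "gatB", "gatC"})
COPY_LABELS = frozenset({"GluRS1", "GluRS2", "unassigned"})

#: The 20 phylum/class codes of the packaged survey; user-extensible via the
#: ``phyla`` argument of :func:`build_inventory`.
DEFAULT_PHYLA = (
    "ad", "ns", "gs", "dt", "ht", "cy", "pl", "ve", "fu", "ba",
    "sp", "ch", "ac", "te", "fi", "alpha", "epsilon", "delta", "gamma", "beta",
)

#: Sentinel returned by :func:`classify_genome` for inventories outside the
#: five legal groups (0 or >2 GluRS copies, or no glutaminylation route).
UNCLASSIFIED = "UNCLASSIFIED"


class InventoryError(ValueError):
    """Malformed gene-occurrence input (unknown gene, conflicting phylum...)."""


class LabelTieError(ValueError):
    """Copy labelling refused because nearest-reference assignment is tied."""


@dataclass(frozen=True)
class GeneOccurrence:
    """One gene found in one genome."""

    genome_id: str
    phylum: str
    gene: str
    copy_label: str | None = None
    pseudogene: bool = False

    def __post_init__(self) -> None:
        if not self.genome_id:
            raise InventoryError("genome_id must be non-empty")
        if self.gene not in GENE_VOCABULARY:
            raise InventoryError(
                f"unknown gene symbol {self.gene!r} in row for genome "
                f"{self.genome_id!r} (expected one of {sorted(GENE_VOCABULARY)})"
            )
        if self.copy_label is not None:
            if self.gene != "gltX":
                raise InventoryError(
                    f"copy_label is only meaningful for gltX rows "
                    f"(genome {self.genome_id!r}, gene {self.gene!r})"
                )
            if self.copy_label not in COPY_LABELS:
                raise InventoryError(f"invalid copy_label {self.copy_label!r}")


@dataclass(frozen=True)
class GenomeInventory:
    """Per-genome gene complement; pseudogenes recorded but never counted."""

    genome_id: str
    phylum: str
    glurs_copies: int
    glnrs_present: bool
    gatcab_present: bool
    copy_labels: tuple[str, ...] = ()
    pseudogenes: tuple[str, ...] = ()


@dataclass(frozen=True)
class GlxGroup:
    """A legal ``<copies|glnS|gatCAB>`` co-occurrence group."""

    copies: int
    glnrs: bool
    gatcab: bool

    #: The five combinations of Table-style co-occurrence classification.
    LEGAL: ClassVar[tuple[tuple[int, bool, bool], ...]] = (
        (1, False, True),
        (2, False, True),
        (2, True, True),
        (1, True, True),
        (1, True, False),
    )

    def __post_init__(self) -> None:
        if (self.copies, self.glnrs, self.gatcab) not in self.LEGAL:
            raise ValueError(
                f"illegal co-occurrence group ({self.copies}, glnrs={self.glnrs}, "
                f"gatcab={self.gatcab}); use UNCLASSIFIED for out-of-scheme genomes"
            )

    def render(self) -> str:
        """ASCII pipe form, e.g. ``'2|-|+'``."""
        return "|".join(
            [str(self.copies), "+" if self.glnrs else "-", "+" if self.gatcab else "-"]
        )

    @classmethod
    def parse(cls, text: str) -> "GlxGroup":
        copies, glnrs, gatcab = text.strip().split("|")
        return cls(int(copies), glnrs == "+", gatcab == "+")

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


#: Functional-type annotations for GluRS copies.
ND_GLURS = "ND-GluRS"
D_MINUS_GLURS = "D(-)-GluRS"
D_PLUS_GLURS = "D(+)-GluRS"
GLURS1 = "GluRS1"
GLURS2 = "GluRS2"

_SINGLE_COPY_TYPE = {
    (1, False, True): ND_GLURS,
    (1, True, False): D_MINUS_GLURS,
    (1, True, True): D_PLUS_GLURS,
}


def build_inventory(
    rows: Iterable[GeneOccurrence],
    phyla: Sequence[str] = DEFAULT_PHYLA,
) -> list[GenomeInventory]:
    """Collapse gene-occurrence rows into one inventory per genome.

    Pseudogene rows are recorded in ``pseudogenes`` but excluded from all
    presence calls and copy counts.  gatCAB presence requires all three of
    gatA/gatB/gatC as non-pseudogenes.

    Raises
    ------
    InventoryError
        If one genome carries conflicting phylum labels, or a phylum code is
        outside the supplied vocabulary.
    """
    vocab = set(phyla)
    by_genome: dict[str, list[GeneOccurrence]] = defaultdict(list)
    order: list[str] = []
    for row in rows:
        if row.phylum not in vocab:
            raise InventoryError(
                f"unknown phylum code {row.phylum!r} for genome {row.genome_id!r}"
            )
        if row.genome_id not in by_genome:
            order.append(row.genome_id)
        by_genome[row.genome_id].append(row)

    inventories = []
    for gid in order:
        genome_rows = by_genome[gid]
        phyla_seen = {r.phylum for r in genome_rows}
        if len(phyla_seen) > 1:
            raise InventoryError(
                f"conflicting phylum labels for genome {gid!r}: {sorted(phyla_seen)}"
            )
        live = [r for r in genome_rows if not r.pseudogene]
        dead = tuple(r.gene for r in genome_rows if r.pseudogene)
        genes = Counter(r.gene for r in live)
        labels = tuple(
            r.copy_label for r in live if r.gene == "gltX" and r.copy_label
        )
        inventories.append(
            GenomeInventory(
                genome_id=gid,
                phylum=phyla_seen.pop(),
                glurs_copies=genes["gltX"],
                glnrs_present=genes["glnS"] > 0,
                gatcab_present=all(genes[g] > 0 for g in ("gatA", "gatB", "gatC")),
                copy_labels=labels,
                pseudogenes=dead,
            )
        )
    return inventories


def classify_genome(inv: GenomeInventory) -> GlxGroup | str:
    """Assign the co-occurrence group, or ``UNCLASSIFIED`` with a warning.

    A genome is unclassifiable when its GluRS copy number is outside {1, 2}
    or when no glutaminylation route exists at all (GlnRS absent and gatCAB
    absent).
    """
    if inv.glurs_copies not in (1, 2):
        logger.warning(
            "genome %s UNCLASSIFIED: %d GluRS copies (expected 1 or 2)",
            inv.genome_id, inv.glurs_copies,
        )
        return UNCLASSIFIED
    if not inv.glnrs_present and not inv.gatcab_present:
        logger.warning(
            "genome %s UNCLASSIFIED: no route to Gln-tRNA(Gln) "
            "(GlnRS and gatCAB both absent)", inv.genome_id,
        )
        return UNCLASSIFIED
    key = (inv.glurs_copies, inv.glnrs_present, inv.gatcab_present)
    if key not in GlxGroup.LEGAL:
        # only remaining illegal combination is (2, glnrs, gatcab=False)
        logger.warning(
            "genome %s UNCLASSIFIED: two GluRS copies without gatCAB",
            inv.genome_id,
        )
        return UNCLASSIFIED
    return GlxGroup(*key)


def assign_functional_types(
    group: GlxGroup,
    copy_labels: Sequence[str] | None = None,
) -> dict[str, str]:
    """Map each GluRS copy to its functional type.

    Single-copy groups map their lone copy (keyed ``'GluRS'``) to
    ND/D(-)/D(+); two-copy groups require explicit GluRS1/GluRS2 labels.
    """
    if group == UNCLASSIFIED or not isinstance(group, GlxGroup):
        raise ValueError("cannot assign functional types to an UNCLASSIFIED genome")
    key = (group.copies, group.glnrs, group.gatcab)
    if group.copies == 1:
        return {"GluRS": _SINGLE_COPY_TYPE[key]}
    labels = [l for l in (copy_labels or ()) if l in ("GluRS1", "GluRS2")]
    if not labels:
        raise ValueError(
            "two-copy genome with unassigned copies: run label_copies() against "
            "annotated reference isoforms before assigning functional types"
        )
    return {label: label for label in ("GluRS1", "GluRS2") if label in labels}


def label_copies(
    seq_a: str,
    seq_b: str,
    refs: Mapping[str, str],
    min_length: int = 280,
) -> dict[str, tuple[str, float]]:
    """Assign GluRS1/GluRS2 labels by nearest annotated reference isoform.

    Both query sequences are globally aligned (BLOSUM62, affine gaps) against
    every labelled reference; each query takes the label of its
    highest-identity reference.  Returns ``{query_key: (label, identity)}``
    with query keys ``'a'`` and ``'b'``.

    Raises
    ------
    ValueError
        If a query is shorter than ``min_length`` (guards against
        catalytic-domain-only fragments) or no references are given.
    LabelTieError
        If both queries are nearest to one identical-scoring reference, or a
        query ties between differently-labelled references.
    """
    if not refs:
        raise ValueError("at least one labelled reference pair is required")
    for name, seq in (("a", seq_a), ("b", seq_b)):
        if len(seq) < min_length:
            raise ValueError(
                f"query {name!r} rejected: length {len(seq)} < minimum core "
                f"length {min_length}"
            )

    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1

    def identity(x: str, y: str) -> float:
        aln = aligner.align(x, y)[0]
        a, b = str(aln[0]), str(aln[1])
        matches = sum(1 for p, q in zip(a, b) if p == q and p != "-")
        return matches / len(a)

    results: dict[str, tuple[str, float]] = {}
    best_ref: dict[str, str] = {}
    for name, seq in (("a", seq_a), ("b", seq_b)):
        scored = sorted(
            ((identity(seq, rseq), rlabel) for rlabel, rseq in refs.items()),
            key=lambda t: (-t[0], t[1]),
        )
        if len(scored) > 1 and scored[0][0] == scored[1][0] and scored[0][1] != scored[1][1]:
            raise LabelTieError(
                f"query {name!r} equidistant from references "
                f"{scored[0][1]!r} and {scored[1][1]!r} (identity {scored[0][0]:.4f}); "
                "assignment refused"
            )
        results[name] = (scored[0][1], scored[0][0])
        best_ref[name] = scored[0][1]
    if (
        len(refs) == 1 or best_ref["a"] == best_ref["b"]
    ) and results["a"] == results["b"]:
        raise LabelTieError(
            f"both queries nearest to reference {best_ref['a']!r} with identical "
            f"identity {results['a'][1]:.4f}; assignment refused"
        )
    return results


def tabulate_groups(invs: Iterable[GenomeInventory]) -> pd.DataFrame:
    """Phylum x group count table (ASCII group columns, int counts).

    Row sums equal per-phylum genome counts; the grand total equals the
    number of genomes.  Unclassifiable genomes land in an ``UNCLASSIFIED``
    column so nothing is silently dropped.
    """
    records = []
    for inv in invs:
        group = classify_genome(inv)
        rendered = group.render() if isinstance(group, GlxGroup) else group
        records.append({"phylum": inv.phylum, "group": rendered})
    if not records:
        return pd.DataFrame()
    df = pd.DataFrame.from_records(records)
    table = df.groupby(["phylum", "group"]).size().unstack(fill_value=0)
    canonical = ["1|-|+", "2|-|+", "2|+|+", "1|+|+", "1|+|-"]
    cols = [c for c in canonical if c in table.columns] + [
        c for c in table.columns if c not in canonical
    ]
    return table[cols]


# ---------------------------------------------------------------------------
# TSV interfaces

_COLUMNS = ["genome_id", "phylum", "gene", "copy_label", "pseudogene"]


def read_inventory(path: str | Path) -> list[GeneOccurrence]:
    """Read gene-occurrence rows from canonical TSV (header required)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise InventoryError(f"inventory TSV missing columns: {missing}")
    rows = []
    for rec in df.itertuples(index=False):
        if rec.pseudogene not in ("true", "false"):
            raise InventoryError(
                f"pseudogene must be 'true' or 'false', got {rec.pseudogene!r} "
                f"(genome {rec.genome_id!r})"
            )
        rows.append(
            GeneOccurrence(
                genome_id=rec.genome_id,
                phylum=rec.phylum,
                gene=rec.gene,
                copy_label=rec.copy_label or None,
                pseudogene=rec.pseudogene == "true",
            )
        )
    return rows


def write_inventory(rows: Iterable[GeneOccurrence], path: str | Path) -> None:
    """Write gene-occurrence rows to canonical TSV (booleans as true/false)."""
    df = pd.DataFrame(
        [
            {
                "genome_id": r.genome_id,
                "phylum": r.phylum,
                "gene": r.gene,
                "copy_label": r.copy_label or "",
                "pseudogene": "true" if r.pseudogene else "false",
            }
            for r in rows
        ],
        columns=_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def write_classification(
    invs: Iterable[GenomeInventory], path: str | Path
) -> pd.DataFrame:
    """Per-genome classification report TSV; returns the frame written."""
    recs = []
    for inv in invs:
        group = classify_genome(inv)
        if isinstance(group, GlxGroup):
            rendered = group.render()
            types = assign_functional_types(
                group, inv.copy_labels if group.copies == 2 else None
            ) if (group.copies == 1 or inv.copy_labels) else {}
        else:
            rendered, types = UNCLASSIFIED, {}
        recs.append(
            {
                "genome_id": inv.genome_id,
                "phylum": inv.phylum,
                "group": rendered,
                "functional_types": ";".join(
                    f"{k}={v}" for k, v in sorted(types.items())
                ),
            }
        )
    df = pd.DataFrame.from_records(recs)
    df.to_csv(path, sep="\t", index=False)
    return df


# ---------------------------------------------------------------------------
# Packaged survey fixture

def load_table1_counts() -> pd.DataFrame:
    """The packaged phylum x group occurrence counts of the 366-genome survey."""
    with resources.files("glxrs.data").joinpath("table1_counts.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def table1_inventory() -> list[GeneOccurrence]:
    """Expand every survey cell into that many synthetic genome row sets.

    Each genome receives the gene rows its group implies: ``copies`` gltX
    rows (labelled GluRS1/GluRS2 when two), a glnS row when GlnRS is present
    and gatA/gatB/gatC rows when gatCAB is present.
    """
    counts = load_table1_counts()
    rows: list[GeneOccurrence] = []
    for rec in counts.itertuples(index=False):
        group = GlxGroup.parse(rec.group)
        tag = rec.group.replace("|", "").replace("+", "p").replace("-", "m")
        for k in range(int(rec.count)):
            gid = f"{rec.code}_{tag}_{k:03d}"
            if group.copies == 2:
                rows.append(GeneOccurrence(gid, rec.code, "gltX", "GluRS1"))
                rows.append(GeneOccurrence(gid, rec.code, "gltX", "GluRS2"))
            else:
                rows.append(GeneOccurrence(gid, rec.code, "gltX"))
            if group.glnrs:
                rows.append(GeneOccurrence(gid, rec.code, "glnS"))
            if group.gatcab:
                for gat in ("gatA", "gatB", "gatC"):
                    rows.append(GeneOccurrence(gid, rec.code, gat))
    return rows


def write_table1_fixture(path: str | Path) -> None:
    """Materialise the expanded survey fixture as ``table1_fixture.tsv``."""
    write_inventory(table1_inventory(), path)
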