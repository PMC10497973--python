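"""Plastome CDS utilities: pseudogene classification, gap-column
filtering, and supermatrix concatenation.

A gene copy is called a pseudogene either for a premature stop codon
(frame-1 translation, plastid/bacterial code: TAA/TAG/TGA) or for a
large deletion (query shorter than a fraction of the reference CDS,
default 50%).  Column filtering drops supermatrix columns gapped in 50%
or more of the samples (inclusive threshold).
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "CdsStatus",
    "Alignment",
    "STOP_CODONS",
    "classify_cds",
    "filter_alignment_columns",
    "concatenate_alignments",
    "status_matrix_tsv",
    "partitions_text",
]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})  # translation table 11

_NUCLEOTIDES = frozenset("ACGTN")
_ALIGNMENT_CHARS = _NUCLEOTIDES | {"-"}

INTACT = "intact"
PREMATURE_STOP = "premature_stop"
LARGE_DELETION = "large_deletion"


@dataclasses.dataclass(frozen=True)
class CdsStatus:
    """Classification of one gene in one sample.

    ``detail`` is the 1-based codon index of the first premature stop,
    or the query/reference length fraction for a large deletion, or
    ``None`` for intact.
    """

    gene: str
    sample: str
    status: str
    detail: float | int | None = None


def _check_nucleotides(seq: str, what: str, allow_gap: bool = False) -> str:
    seq = seq.upper()
    if not seq:
        raise ValueError(f"{what} sequence is empty")
    allowed = _ALIGNMENT_CHARS if allow_gap else _NUCLEOTIDES
    bad = set(seq) - allowed
    if bad:
        raise ValueError(f"{what} has non-nucleotide characters: {sorted(bad)}")
    return seq


def classify_cds(
    query: str,
    reference: str,
    deletion_threshold: float = 0.5,
    gene: str = "",
    sample: str = "",
) -> CdsStatus:
    """Classify one CDS copy as intact / premature_stop / large_deletion.

    The reference length must be a positive multiple of 3; the query is
    an ungapped extraction.  Queries shorter than ``deletion_threshold``
    x reference length are large deletions; otherwise the query is
    scanned in frame 1 and a stop codon strictly before its final codon
    is a premature stop.  A missing terminal stop does not disqualify an
    otherwise intact gene (edge-trimmed annotations are tolerated).
    """
    query = _check_nucleotides(query, "query")
    reference = _check_nucleotides(reference, "reference")
    if len(reference) % 3 != 0:
        raise ValueError("reference length must be a multiple of 3")
    if len(query) < deletion_threshold * len(reference):
        return CdsStatus(gene, sample, LARGE_DELETION, len(query) / len(reference))
    n_codons = len(query) // 3
    for i in range(n_codons - 1):  # strictly before the final codon
        if query[3 * i : 3 * i + 3] in STOP_CODONS:
            return CdsStatus(gene, sample, PREMATURE_STOP, i + 1)
    return CdsStatus(gene, sample, INTACT, None)


# ---------------------------------------------------------------------
# Alignments


@dataclasses.dataclass
class Alignment:
    """Equal-length sequences over {A,C,G,T,N,-} with per-column
    provenance retained through filtering and concatenation."""

    names: list[str]
    sequences: list[str]
    columns: list[tuple[str, int]] = dataclasses.field(default_factory=list)
    name: str = ""

    def __post_init__(self):
        if len(self.names) != len(self.sequences):
            raise ValueError("names and sequences differ in number")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate sample names")
        if not self.names:
            raise ValueError("alignment has no samples")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError("ragged alignment: unequal sequence lengths")
        self.sequences = [
            _check_nucleotides(s, "aligned", allow_gap=True) if s else s
            for s in self.sequences
        ]
        if not self.columns:
            self.columns = [(self.name, i + 1) for i in range(self.width)]
        elif len(self.columns) != self.width:
            raise ValueError("column provenance length mismatch")

    @property
    def width(self) -> int:
        return len(self.sequences[0])

    @property
    def n_samples(self) -> int:
        return len(self.names)

    @classmethod
    def from_fasta(cls, path: str, name: str = "") -> "Alignment":
        records = list(SeqIO.parse(path, "fasta"))
        if not records:
            raise ValueError(f"no sequences in {path}")
        return cls(
            names=[r.id for r in records],
            sequences=[str(r.seq) for r in records],
            name=name,
        )

    def to_fasta(self, path: str) -> None:
        with open(path, "w") as fh:
            for n, s in zip(self.names, self.sequences):
                fh.write(f">{n}\n{s}\n")


def filter_alignment_columns(
    aln: Alignment, max_gap_fraction: float = 0.5
) -> Alignment:
    """Drop columns gapped in ``max_gap_fraction`` or more of the
    samples (inclusive: a column with exactly 50% gaps is removed under
    the default).  Row order and column provenance are preserved."""
    n = aln.n_samples
    keep = [
        c
        for c in range(aln.width)
        if sum(1 for s in aln.sequences if s[c] == "-") / n < max_gap_fraction
    ]
    return Alignment(
        names=list(aln.names),
        sequences=["".join(s[c] for c in keep) for s in aln.sequences],
        columns=[aln.columns[c] for c in keep],
        name=aln.name,
    )


def concatenate_alignments(
    gene_alignments: Sequence[Alignment],
) -> tuple[Alignment, list[tuple[str, int, int]]]:
    """Concatenate gene alignments row-wise in list order.

    Samples missing from a gene get an all-gap block for it.  Returns
    the supermatrix and a partition table of 1-based inclusive
    (gene, start, end) spans; total width is the sum of gene widths.
    """
    if not gene_alignments:
        raise ValueError("nothing to concatenate")
    gene_names = [a.name or f"gene{i + 1}" for i, a in enumerate(gene_alignments)]
    if len(set(gene_names)) != len(gene_names):
        raise ValueError("duplicate gene names")

    sample_order: list[str] = []
    for a in gene_alignments:
        for n in a.names:
            if n not in sample_order:
                sample_order.append(n)

    rows = {n: [] for n in sample_order}
    columns: list[tuple[str, int]] = []
    partitions: list[tuple[str, int, int]] = []
    pos = 0
    for gname, a in zip(gene_names, gene_alignments):
        lookup = dict(zip(a.names, a.sequences))
        gap_block = "-" * a.width
        for n in sample_order:
            rows[n].append(lookup.get(n, gap_block))
        # preserve per-gene column indices through prior filtering
        columns.extend((gname, idx) for _, idx in a.columns)
        partitions.append((gname, pos + 1, pos + a.width))
        pos += a.width

    supermatrix = Alignment(
        names=sample_order,
        sequences=["".join(rows[n]) for n in sample_order],
        columns=columns,
        name="concatenated",
    )
    return supermatrix, partitions


def partitions_text(partitions: Iterable[tuple[str, int, int]]) -> str:
    """RAxML-style partition lines: ``GENE = start-end``."""
    return "".join(f"{g} = {s}-{e}\n" for g, s, e in partitions)


def status_matrix_tsv(statuses: Iterable[CdsStatus]) -> str:
    """Genes x samples TSV of status labels (Fig.-style matrix)."""
    by_gene: dict[str, dict[str, str]] = {}
    samples: list[str] = []
    for st in statuses:
        by_gene.setdefault(st.gene, {})[st.sample] = st.status
        if st.sample not in samples:
            samples.append(st.sample)
    lines = ["gene\t" + "\t".join(samples)]
    for gene in by_gene:
        row = [by_gene[gene].get(s, "NA") for s in samples]
        lines.append(gene + "\t" + "\t".join(row))
    return "\n".join(lines) + "\n"
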