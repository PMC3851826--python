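"""Read and write per-accession nucleotide count data (the ALR dialect).

An ALR file stores, for every contig of an assembly, the number of A/C/G/T
bases observed at each reference position in the read mapping of each
accession.  This per-accession count matrix is the sole input of the
homeolog splitter: it is far more informative than called genotypes but
much lighter than the reads themselves.

Dialect (text, UTF-8, tab-separated), one block per contig::

    ><contig_id>
    #accessions<TAB>id1,id2,...,idM        (identical in every block)
    <pos><TAB><ref base><TAB>a/c/g/t<TAB>...<TAB>a/c/g/t   (M count fields)

Positions are 1-based and consecutive in files; all in-memory site indices
are 0-based.  Count fields are four non-negative integers joined by "/" in
A/C/G/T order.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam
from Bio import SeqIO

logger = logging.getLogger(__name__)

_VALID_REF_BASES = set("ACGTN")


class AlrParseError(ValueError):
    """Malformed ALR input; carries the 1-based line number."""

    def __init__(self, path, line_no: int, message: str):
        super().__init__(f"{path}:{line_no}: {message}")
        self.path = path
        self.line_no = line_no


@dataclass
class ContigCounts:
    """Per-accession, per-site nucleotide counts for one contig.

    ``counts`` is the M x N x 4 integer array of observed bases, with the
    nucleotide axis ordered A, C, G, T (1-based indices 1..4 elsewhere in
    the package).  ``ref_seq`` is the contig consensus the reads were
    mapped on (uppercase A/C/G/T/N), of length N.
    """

    contig_id: str
    accession_ids: Sequence[str]
    ref_seq: str
    counts: np.ndarray

    def __post_init__(self):
        self.accession_ids = list(self.accession_ids)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 3 or self.counts.shape[2] != 4:
            raise ValueError(
                f"counts must be M x N x 4, got shape {self.counts.shape}"
            )
        m, n, _ = self.counts.shape
        if len(self.accession_ids) != m:
            raise ValueError("accession_ids length does not match counts")
        if len(set(self.accession_ids)) != m:
            raise ValueError("accession_ids must be unique")
        self.ref_seq = self.ref_seq.upper()
        if len(self.ref_seq) != n:
            raise ValueError("ref_seq length does not match counts")
        if not set(self.ref_seq) <= _VALID_REF_BASES:
            bad = sorted(set(self.ref_seq) - _VALID_REF_BASES)
            raise ValueError(f"ref_seq contains invalid characters: {bad}")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_accessions(self) -> int:
        return self.counts.shape[0]

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    def site_coverage(self) -> np.ndarray:
        """Total coverage per site summed over accessions (length N)."""
        return self.counts.sum(axis=(0, 2))

    def accession_coverage(self) -> np.ndarray:
        """Per-accession coverage at each site (M x N)."""
        return self.counts.sum(axis=2)

    def mean_coverage(self) -> float:
        """Average total coverage per site (0.0 for an empty contig)."""
        if self.length == 0:
            return 0.0
        return float(self.site_coverage().mean())


@dataclass
class AlrDataset:
    """Ordered collection of contigs sharing one accession panel."""

    contigs: list[ContigCounts] = field(default_factory=list)

    def __post_init__(self):
        ids = [c.contig_id for c in self.contigs]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate contig ids in dataset")
        if self.contigs:
            ref = self.contigs[0].accession_ids
            for c in self.contigs[1:]:
                if c.accession_ids != ref:
                    raise ValueError(
                        f"contig {c.contig_id!r} has a different accession panel"
                    )

    @property
    def accession_ids(self) -> list[str]:
        return self.contigs[0].accession_ids if self.contigs else []

    def __iter__(self):
        return iter(self.contigs)

    def __len__(self) -> int:
        return len(self.contigs)

    def get(self, contig_id: str) -> ContigCounts:
        for c in self.contigs:
            if c.contig_id == contig_id:
                return c
        raise KeyError(contig_id)


def _parse_count_field(text: str, path, line_no: int) -> list[int]:
    parts = text.split("/")
    if len(parts) != 4:
        raise AlrParseError(path, line_no, f"count field {text!r} is not a/c/g/t")
    try:
        values = [int(p) for p in parts]
    except ValueError:
        raise AlrParseError(path, line_no, f"non-integer count in {text!r}") from None
    if any(v < 0 for v in values):
        raise AlrParseError(path, line_no, f"negative count in {text!r}")
    return values


def read_alr(path) -> AlrDataset:
    """Parse an ALR file into an :class:`AlrDataset`.

    Raises :class:`AlrParseError` (with the offending 1-based line number)
    on malformed headers, inconsistent field counts, negative counts or
    duplicate contig ids.
    """
    path = Path(path)
    contigs: list[ContigCounts] = []
    seen_ids: set[str] = set()
    panel: list[str] | None = None

    with open(path, encoding="utf-8") as handle:
        lines = handle.read().splitlines()

    i = 0
    n_lines = len(lines)
    while i < n_lines:
        line = lines[i]
        if not line.strip():
            i += 1
            continue
        if not line.startswith(">"):
            raise AlrParseError(path, i + 1, f"expected '>' contig header, got {line!r}")
        contig_id = line[1:].strip()
        if not contig_id:
            raise AlrParseError(path, i + 1, "empty contig id")
        if contig_id in seen_ids:
            raise AlrParseError(path, i + 1, f"duplicate contig id {contig_id!r}")
        seen_ids.add(contig_id)
        i += 1
        if i >= n_lines or not lines[i].startswith("#accessions\t"):
            raise AlrParseError(path, i + 1, "expected '#accessions' line")
        ids = lines[i].split("\t", 1)[1].split(",")
        ids = [a.strip() for a in ids]
        if panel is None:
            panel = ids
        elif ids != panel:
            raise AlrParseError(path, i + 1, "accession panel differs between blocks")
        i += 1

        ref_bases: list[str] = []
        rows: list[list[list[int]]] = []
        expected_pos = 1
        while i < n_lines and lines[i].strip() and not lines[i].startswith(">"):
            fields = lines[i].split("\t")
            if len(fields) != 2 + len(panel):
                raise AlrParseError(
                    path, i + 1,
                    f"expected {2 + len(panel)} tab-separated fields, got {len(fields)}",
                )
            try:
                pos = int(fields[0])
            except ValueError:
                raise AlrParseError(path, i + 1, f"invalid position {fields[0]!r}") from None
            if pos != expected_pos:
                raise AlrParseError(
                    path, i + 1, f"expected position {expected_pos}, got {pos}"
                )
            base = fields[1].strip().upper()
            if len(base) != 1 or base not in _VALID_REF_BASES:
                raise AlrParseError(path, i + 1, f"invalid reference base {fields[1]!r}")
            ref_bases.append(base)
            rows.append([_parse_count_field(f, path, i + 1) for f in fields[2:]])
            expected_pos += 1
            i += 1

        counts = (
            np.array(rows, dtype=np.int64).transpose(1, 0, 2)
            if rows
            else np.zeros((len(panel), 0, 4), dtype=np.int64)
        )
        contigs.append(
            ContigCounts(contig_id, list(panel), "".join(ref_bases), counts)
        )

    if panel is None:
        return AlrDataset([])
    return AlrDataset(contigs)


def write_alr(dataset: AlrDataset, path) -> None:
    """Write an :class:`AlrDataset` in the canonical ALR dialect.

    Contigs and accessions are written in stored order; the output
    round-trips through :func:`read_alr` field-by-field.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8") as handle:
        for contig in dataset:
            handle.write(f">{contig.contig_id}\n")
            handle.write("#accessions\t" + ",".join(contig.accession_ids) + "\n")
            for s in range(contig.length):
                fields = [str(s + 1), contig.ref_seq[s]]
                for a in range(contig.n_accessions):
                    fields.append("/".join(str(v) for v in contig.counts[a, s]))
                handle.write("\t".join(fields) + "\n")


def sam_to_alr(
    sam_paths: Sequence,
    ref_fasta,
    min_base_quality: int = 20,
    min_mapping_quality: int = 10,
    accession_ids: Sequence[str] | None = None,
) -> AlrDataset:
    """Pileup-count SAM/BAM mappings into an :class:`AlrDataset`.

    One SAM/BAM file per accession (file identity = accession identity;
    read groups are ignored).  A base contributes to ``counts[a][s][n]``
    when its read maps with mapping quality >= ``min_mapping_quality``,
    the base quality is >= ``min_base_quality`` and the base is A/C/G/T
    aligned to reference position ``s`` (deletions, insertions, Ns and
    clipped bases contribute nothing).  Secondary, supplementary,
    duplicate and QC-failed alignments are skipped.
    """
    sam_paths = [Path(p) for p in sam_paths]
    if accession_ids is None:
        accession_ids = [p.stem for p in sam_paths]
    accession_ids = list(accession_ids)
    if len(set(accession_ids)) != len(accession_ids):
        raise ValueError("accession ids derived from SAM paths are not unique")

    refs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(ref_fasta), "fasta")}
    if not refs:
        raise ValueError(f"no sequences in reference FASTA {ref_fasta}")
    ref_order = list(refs)
    counts = {
        name: np.zeros((len(sam_paths), len(seq), 4), dtype=np.int64)
        for name, seq in refs.items()
    }
    base_index = np.full(256, -1, dtype=np.int64)
    for i, b in enumerate("ACGT"):
        base_index[ord(b)] = i
        base_index[ord(b.lower())] = i

    for a, sam_path in enumerate(sam_paths):
        any_mapped = False
        with pysam.AlignmentFile(str(sam_path), check_sq=False) as sam:
            for sq in sam.header.get("SQ", []):
                name = sq["SN"]
                if name not in refs:
                    raise ValueError(
                        f"{sam_path}: reference {name!r} absent from FASTA"
                    )
                if sq.get("LN") not in (None, len(refs[name])):
                    raise ValueError(
                        f"{sam_path}: length of reference {name!r} does not match FASTA"
                    )
            for read in sam.fetch(until_eof=True):
                if (
                    read.is_unmapped
                    or read.is_secondary
                    or read.is_supplementary
                    or read.is_duplicate
                    or read.is_qcfail
                ):
                    continue
                if read.mapping_quality < min_mapping_quality:
                    continue
                any_mapped = True
                target = counts[read.reference_name]
                seq = read.query_sequence
                quals = read.query_qualities
                for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                    if quals is not None and quals[qpos] < min_base_quality:
                        continue
                    n = base_index[ord(seq[qpos])]
                    if n >= 0:
                        target[a, rpos, n] += 1
        if not any_mapped:
            warnings.warn(f"{sam_path}: no mapped reads passed the filters")

    contigs = [
        ContigCounts(name, accession_ids, refs[name], counts[name])
        for name in ref_order
    ]
    return AlrDataset(contigs)


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 80) -> None:
    """Write (id, sequence) records as 80-column-wrapped FASTA.

    Split contigs are conventionally named ``<contig_id>_1`` (the Ck1
    pattern) and ``<contig_id>_2`` (its complement).
    """
    records = list(records)
    ids = [rid for rid, _ in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate record ids")
    for rid, seq in records:
        if not seq:
            raise ValueError(f"empty sequence for record {rid!r}")
    with open(path, "w", encoding="utf-8") as handle:
        for rid, seq in records:
            handle.write(f">{rid}\n")
            for start in range(0, len(seq), width):
                handle.write(seq[start : start + width] + "\n")
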