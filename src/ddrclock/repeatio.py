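"""Sequence and alignment I/O for direct-repeat analysis.

Reads and writes aligned FASTA, builds validated repeat pairs, and threads
codons from an unaligned CDS onto a protein alignment so that nucleotide
alignments inherit the (usually much more reliable) amino-acid alignment.

Coordinates are 0-based half-open internally; anything user-facing
(error messages, reports) is 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NT_ALPHABET = set("ACGTN-")
AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX-")
#: characters treated as non-comparable (excluded like gaps downstream)
AMBIGUOUS = set("NX-")

Domain = Literal["euryarchaeota", "crenarchaeota", "eukaryote", "unknown"]
DOMAINS = ("euryarchaeota", "crenarchaeota", "eukaryote", "unknown")


class SequenceError(ValueError):
    """Malformed sequence input (bad alphabet, bad lengths, empty data)."""


@dataclass(frozen=True)
class SeqRecordNT:
    """A single (possibly aligned) nucleotide or protein sequence."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("record id must be nonempty")
        if not self.seq:
            raise SequenceError(f"record {self.id!r}: sequence is empty")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def ungapped(self) -> str:
        return self.seq.replace("-", "")


@dataclass(frozen=True)
class RepeatPair:
    """One gene's aligned first and second repeat copies.

    The two sequences must come from the same pairwise/multiple alignment
    (equal aligned length). ``domain`` is user metadata mirroring the
    archaeal/eukaryotic grouping of the source table.
    """

    gene_id: str
    species: str
    domain: Domain
    first: SeqRecordNT
    second: SeqRecordNT

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise SequenceError(
                f"gene {self.gene_id!r}: unknown domain {self.domain!r}"
            )
        if len(self.first.seq) != len(self.second.seq):
            raise SequenceError(
                f"gene {self.gene_id!r}: aligned lengths differ "
                f"({len(self.first.seq)} vs {len(self.second.seq)})"
            )
        for rec in (self.first, self.second):
            if not rec.ungapped:
                raise SequenceError(
                    f"gene {self.gene_id!r}: record {rec.id!r} is all gaps"
                )


@dataclass(frozen=True)
class RecordMeta:
    gene: str
    repeat_index: int  # 1 or 2
    species: str
    domain: Domain = "unknown"


@dataclass
class AlignmentSet:
    """An ordered multiple alignment with per-record repeat metadata."""

    records: list[SeqRecordNT]
    metadata: dict[str, RecordMeta] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.records:
            raise SequenceError("alignment set is empty")
        length = len(self.records[0].seq)
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise SequenceError(f"duplicate record id {rec.id!r}")
            seen.add(rec.id)
            if len(rec.seq) != length:
                raise SequenceError(
                    f"record {rec.id!r}: length {len(rec.seq)} != {length}"
                )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def length(self) -> int:
        return len(self.records[0].seq)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def get(self, record_id: str) -> SeqRecordNT:
        for rec in self.records:
            if rec.id == record_id:
                return rec
        raise KeyError(record_id)


def _validate_alphabet(seq: str, alphabet: set[str], record_id: str) -> None:
    for i, ch in enumerate(seq):
        if ch not in alphabet:
            raise SequenceError(
                f"record {record_id!r}: invalid character {ch!r} "
                f"at column {i + 1}"
            )


def read_fasta(path: str | Path, alphabet: Literal["nt", "aa"] = "nt") -> list[SeqRecordNT]:
    """Read a (plain or aligned) FASTA file.

    Characters are uppercased; for nucleotides, RNA 'U' is mapped to 'T'.
    Only {A,C,G,T,N,-} (nt) or the 20 amino acids plus {X,-} (aa) are
    accepted; anything else is rejected with the offending record and
    1-based column.
    """
    records: list[SeqRecordNT] = []
    allowed = NT_ALPHABET if alphabet == "nt" else AA_ALPHABET
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if alphabet == "nt":
            seq = seq.replace("U", "T")
        _validate_alphabet(seq, allowed, rec.id)
        records.append(SeqRecordNT(id=rec.id, seq=seq))
    if not records:
        raise SequenceError(f"{path}: no FASTA records found")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dup = next(i for i in ids if ids.count(i) > 1)
        raise SequenceError(f"{path}: duplicate record id {dup!r}")
    return records


def write_fasta(records: Iterable[SeqRecordNT], path: str | Path, width: int = 70) -> None:
    bio = [SeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def write_phylip(records: list[SeqRecordNT], path: str | Path) -> None:
    """Write a relaxed sequential PHYLIP alignment (output only)."""
    length = len(records[0].seq)
    for rec in records:
        if len(rec.seq) != length:
            raise SequenceError("phylip output requires equal-length records")
    with open(path, "w") as fh:
        fh.write(f" {len(records)} {length}\n")
        for rec in records:
            fh.write(f"{rec.id}  {rec.seq}\n")


_CODON_TABLE = None


def _translate_codon(codon: str) -> str:
    global _CODON_TABLE
    if _CODON_TABLE is None:
        from Bio.Data import CodonTable

        _CODON_TABLE = CodonTable.standard_dna_table.forward_table
    return _CODON_TABLE.get(codon, "*")


def thread_codons(
    nt: SeqRecordNT,
    aa_aligned: str,
    mismatch_tolerance: int = 0,
) -> SeqRecordNT:
    """Thread an unaligned CDS onto an aligned amino-acid sequence.

    Each residue in ``aa_aligned`` is replaced by its source codon from
    ``nt`` and each gap by ``---``, producing a codon-aware nucleotide
    alignment of length ``3 * len(aa_aligned)``. The CDS must translate to
    the ungapped protein under the standard genetic code; up to
    ``mismatch_tolerance`` codon/residue disagreements are permitted
    (default 0).
    """
    aa_aligned = aa_aligned.upper()
    aa_ungapped = aa_aligned.replace("-", "")
    cds = nt.ungapped
    if len(cds) != 3 * len(aa_ungapped):
        raise SequenceError(
            f"record {nt.id!r}: CDS length {len(cds)} != 3 x "
            f"{len(aa_ungapped)} protein residues"
        )
    mismatches = []
    for i, res in enumerate(aa_ungapped):
        codon = cds[3 * i : 3 * i + 3]
        if "N" in codon:
            continue
        if _translate_codon(codon) != res and res != "X":
            mismatches.append((i + 1, codon, res))
    if len(mismatches) > mismatch_tolerance:
        idx, codon, res = mismatches[0]
        raise SequenceError(
            f"record {nt.id!r}: codon {idx} ({codon}) does not translate to "
            f"{res!r} ({len(mismatches)} mismatching codon(s) in total)"
        )
    out = []
    k = 0
    for ch in aa_aligned:
        if ch == "-":
            out.append("---")
        else:
            out.append(cds[3 * k : 3 * k + 3])
            k += 1
    return SeqRecordNT(id=nt.id, seq="".join(out))


def build_repeat_pair(
    gene_id: str,
    species: str,
    domain: Domain,
    first_aligned: SeqRecordNT,
    second_aligned: SeqRecordNT,
) -> RepeatPair:
    """Validate and assemble a RepeatPair (equal lengths, not all-gap)."""
    return RepeatPair(
        gene_id=gene_id,
        species=species,
        domain=domain,
        first=first_aligned,
        second=second_aligned,
    )


def alignment_set_from_pairs(pairs: Iterable[RepeatPair]) -> AlignmentSet:
    """Stack repeat pairs into the joint first+second alignment used by the
    single-duplication test. Record ids become ``<gene>__r1``/``<gene>__r2``."""
    records: list[SeqRecordNT] = []
    metadata: dict[str, RecordMeta] = {}
    for pair in pairs:
        for idx, rec in ((1, pair.first), (2, pair.second)):
            rid = f"{pair.gene_id}__r{idx}"
            records.append(SeqRecordNT(id=rid, seq=rec.seq))
            metadata[rid] = RecordMeta(
                gene=pair.gene_id,
                repeat_index=idx,
                species=pair.species,
                domain=pair.domain,
            )
    return AlignmentSet(records=records, metadata=metadata)


def read_metadata(path: str | Path) -> dict[str, RecordMeta]:
    """Read a tab-separated metadata table: id, gene, repeat_index, species[, domain]."""
    meta: dict[str, RecordMeta] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "id":  # header
                continue
            if len(parts) < 4:
                raise SequenceError(f"{path}:{lineno}: expected >=4 columns")
            rid, gene, ridx, species = parts[:4]
            domain = parts[4] if len(parts) > 4 else "unknown"
            if ridx not in ("1", "2"):
                raise SequenceError(
                    f"{path}:{lineno}: repeat_index must be 1 or 2, got {ridx!r}"
                )
            meta[rid] = RecordMeta(gene, int(ridx), species, domain)  # type: ignore[arg-type]
    return meta


def write_metadata(meta: dict[str, RecordMeta], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tgene\trepeat_index\tspecies\tdomain\n")
        for rid, m in meta.items():
            fh.write(f"{rid}\t{m.gene}\t{m.repeat_index}\t{m.species}\t{m.domain}\n")
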