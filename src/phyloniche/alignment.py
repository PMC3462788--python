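"""Aligned-sequence containers, FASTA I/O, concatenation and haplotype collapsing.

An :class:`Alignment` holds equal-length nucleotide sequences over the strict
alphabet ``{A, C, G, T, N, -}``.  IUPAC ambiguity codes (R, Y, S, W, ...) are
rejected outright: silently coercing them to N changes haplotype counts, and
different haplotype-collapsing programs disagree on how to treat them, so the
caller must resolve ambiguities before import.

Haplotype collapsing follows the convention of DnaSP-style pipelines: under the
default ``complete_sites`` policy every column containing a gap or N in *any*
sequence is removed before sequences are compared, and sequences identical at
the retained columns share a haplotype.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._errors import AlphabetError, DegenerateInputError, ValidationError

VALID_CHARS = frozenset("ACGTN-")

SitePolicy = Literal["complete_sites", "pairwise"]


@dataclass
class Alignment:
    """Equal-length nucleotide sequences with unique sample IDs.

    ``matrix`` is a 2-D array of single characters with shape
    ``(n_samples, n_sites)``; sequences are stored uppercase.
    """

    sample_ids: list[str]
    matrix: np.ndarray
    locus_name: str = "locus"

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(set(self.sample_ids)):
            dupes = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise ValidationError(f"duplicate sample IDs: {dupes}")
        self.matrix = np.asarray(self.matrix, dtype="U1")
        if self.matrix.ndim != 2:
            raise ValidationError("alignment matrix must be 2-D (samples x sites)")
        if self.matrix.shape[0] != len(self.sample_ids):
            raise ValidationError(
                f"{len(self.sample_ids)} sample IDs but {self.matrix.shape[0]} rows"
            )
        if self.n_sites == 0 and self.n_samples > 0:
            # zero-length sequences are tolerated only as concatenation identities
            pass
        bad = set(np.unique(self.matrix)) - VALID_CHARS
        if bad:
            raise AlphabetError(
                f"invalid characters {sorted(bad)}; allowed: A,C,G,T,N,- "
                "(IUPAC ambiguity codes must be resolved before import)"
            )

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def sequence(self, sample_id: str) -> str:
        i = self.sample_ids.index(sample_id)
        return "".join(self.matrix[i])

    def sequences(self) -> list[str]:
        return ["".join(row) for row in self.matrix]

    def subset(self, sample_ids: Iterable[str]) -> "Alignment":
        """Row-subset in the given order; unknown IDs raise."""
        ids = list(sample_ids)
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in index]
        if missing:
            raise ValidationError(f"unknown sample IDs: {missing}")
        rows = [index[s] for s in ids]
        return Alignment(ids, self.matrix[rows], self.locus_name)

    @classmethod
    def from_sequences(
        cls, sample_ids: Iterable[str], seqs: Iterable[str], locus_name: str = "locus"
    ) -> "Alignment":
        ids = list(sample_ids)
        seqs = [s.upper() for s in seqs]
        if not ids:
            raise ValidationError("empty alignment")
        lengths = {len(s) for s in seqs}
        if len(lengths) > 1:
            offender = next(s_id for s_id, s in zip(ids, seqs) if len(s) != len(seqs[0]))
            raise ValidationError(
                f"ragged alignment: record '{offender}' has length "
                f"{len(dict(zip(ids, seqs))[offender])}, expected {len(seqs[0])}"
            )
        mat = np.array([list(s) for s in seqs], dtype="U1") if seqs[0] else np.empty(
            (len(ids), 0), dtype="U1"
        )
        return cls(ids, mat, locus_name)


@dataclass
class PopulationAssignment:
    """sample -> population mapping, with optional population -> group layer."""

    sample_to_pop: dict[str, str]
    pop_to_group: dict[str, str] | None = None

    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.sample_to_pop.values():
            seen.setdefault(p)
        return list(seen)

    def groups(self) -> list[str]:
        if self.pop_to_group is None:
            raise ValidationError("no group layer defined")
        seen: dict[str, None] = {}
        for g in self.pop_to_group.values():
            seen.setdefault(g)
        return list(seen)

    def samples_in_pop(self, pop: str) -> list[str]:
        return [s for s, p in self.sample_to_pop.items() if p == pop]

    def pops_in_group(self, group: str) -> list[str]:
        if self.pop_to_group is None:
            raise ValidationError("no group layer defined")
        return [p for p, g in self.pop_to_group.items() if g == group]

    def validate_against(self, aln: Alignment) -> None:
        missing = [s for s in aln.sample_ids if s not in self.sample_to_pop]
        if missing:
            raise ValidationError(f"samples without population assignment: {missing}")
        if self.pop_to_group is not None:
            pops = set(self.populations())
            uncovered = sorted(pops - set(self.pop_to_group))
            if uncovered:
                raise ValidationError(f"populations without group: {uncovered}")

    def with_groups(self, pop_to_group: dict[str, str]) -> "PopulationAssignment":
        return PopulationAssignment(dict(self.sample_to_pop), dict(pop_to_group))


@dataclass
class HaplotypeTable:
    """Distinct sequence classes and their per-population frequency spectrum."""

    haplotype_seqs: list[str]
    assignment: dict[str, int]  # sample_id -> haplotype index
    counts_by_population: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotype_seqs)

    @property
    def n_samples(self) -> int:
        return len(self.assignment)

    def total_counts(self) -> np.ndarray:
        counts = np.zeros(self.n_haplotypes, dtype=int)
        for h in self.assignment.values():
            counts[h] += 1
        return counts

    def counts_for(self, population: str) -> np.ndarray:
        return self.counts_by_population[population]


def read_fasta_alignment(path, locus_name: str | None = None) -> Alignment:
    """Read a FASTA file as an alignment; every record must have equal length."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise DegenerateInputError(f"no FASTA records found in {path}")
    ids = [r.id for r in records]
    seqs = [str(r.seq).upper() for r in records]
    ref_len = len(seqs[0])
    for rid, s in zip(ids, seqs):
        if len(s) != ref_len:
            raise ValidationError(
                f"ragged alignment: record '{rid}' has length {len(s)}, "
                f"expected {ref_len} (from '{ids[0]}')"
            )
    name = locus_name if locus_name is not None else "locus"
    return Alignment.from_sequences(ids, seqs, name)


def write_fasta_alignment(aln: Alignment, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=sid, description="")
        for sid, seq in zip(aln.sample_ids, aln.sequences())
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta-2line")


def concatenate(a: Alignment, b: Alignment) -> Alignment:
    """Join two loci sample-by-sample (matched on ID, not row order)."""
    set_a, set_b = set(a.sample_ids), set(b.sample_ids)
    if set_a != set_b:
        only_a = sorted(set_a - set_b)
        only_b = sorted(set_b - set_a)
        raise ValidationError(
            f"sample ID sets differ: only in {a.locus_name}: {only_a}; "
            f"only in {b.locus_name}: {only_b}"
        )
    b_aligned = b.subset(a.sample_ids)
    mat = np.concatenate([a.matrix, b_aligned.matrix], axis=1)
    return Alignment(list(a.sample_ids), mat, f"{a.locus_name}+{b.locus_name}")


def complete_site_mask(aln: Alignment) -> np.ndarray:
    """Boolean mask of columns free of gaps and Ns in every sequence."""
    return ~np.any((aln.matrix == "-") | (aln.matrix == "N"), axis=0)


def collapse_haplotypes(
    aln: Alignment,
    pops: PopulationAssignment | None = None,
    site_policy: SitePolicy = "complete_sites",
) -> HaplotypeTable:
    """Collapse identical sequences into haplotypes.

    Under ``complete_sites`` (the default, matching listwise deletion of
    gap/N columns) all columns with a gap or N in any sequence are removed
    before comparison.  Under ``pairwise`` the full sequences are compared
    verbatim (N and - treated as states), which never merges sequences that
    ``complete_sites`` would keep apart.
    """
    if aln.n_samples == 0:
        raise DegenerateInputError("empty alignment")
    if site_policy == "complete_sites":
        keep = complete_site_mask(aln)
        if not keep.any():
            raise DegenerateInputError(
                "complete_sites policy retained zero columns (every site has a gap or N)"
            )
        working = aln.matrix[:, keep]
    elif site_policy == "pairwise":
        working = aln.matrix
    else:
        raise ValueError(f"unknown site_policy: {site_policy!r}")

    key_to_index: dict[str, int] = {}
    assignment: dict[str, int] = {}
    rep_full: list[str] = []
    for sid, row, full in zip(aln.sample_ids, working, aln.sequences()):
        key = "".join(row)
        if key not in key_to_index:
            key_to_index[key] = len(key_to_index)
            rep_full.append(full)
        assignment[sid] = key_to_index[key]

    counts_by_population: dict[str, np.ndarray] = {}
    if pops is not None:
        pops.validate_against(aln)
        for pop in pops.populations():
            vec = np.zeros(len(key_to_index), dtype=int)
            for sid in pops.samples_in_pop(pop):
                if sid in assignment:
                    vec[assignment[sid]] += 1
            counts_by_population[pop] = vec
    return HaplotypeTable(rep_full, assignment, counts_by_population)


def polymorphic_sites(aln: Alignment) -> tuple[int, list[int]]:
    """Count segregating sites; a site is polymorphic iff >=2 distinct
    nucleotides among {A,C,G,T} occur there (gap/N excluded from the state
    count).  Positions are 1-based."""
    if aln.n_samples == 0:
        raise DegenerateInputError("empty alignment")
    positions = []
    for j in range(aln.n_sites):
        col = aln.matrix[:, j]
        states = set(col) & {"A", "C", "G", "T"}
        if len(states) >= 2:
            positions.append(j + 1)
    return len(positions), positions


# ---------------------------------------------------------------------------
# delimited-text interfaces

def read_population_table(path) -> dict[str, str]:
    """Two-column TSV (sample_id, population); '#' comment lines skipped."""
    return _read_two_col(path, "sample/population")


def read_group_table(path) -> dict[str, str]:
    """Two-column TSV (population, group)."""
    return _read_two_col(path, "population/group")


def _read_two_col(path, what: str) -> dict[str, str]:
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValidationError(f"{what} table line {ln}: expected 2 columns")
            key, value = parts
            if key in mapping and mapping[key] != value:
                raise ValidationError(f"{what} table: conflicting entries for '{key}'")
            mapping[key] = value
    if not mapping:
        raise DegenerateInputError(f"empty {what} table")
    return mapping


def read_assignment(sample_pop_path, pop_group_path=None) -> PopulationAssignment:
    s2p = read_population_table(sample_pop_path)
    p2g = read_group_table(pop_group_path) if pop_group_path is not None else None
    return PopulationAssignment(s2p, p2g)


def write_haplotype_table(table: HaplotypeTable, path) -> None:
    """TSV: haplotype_id, sequence, total_count, then one column per population."""
    pops = list(table.counts_by_population)
    totals = table.total_counts()
    with open(path, "w") as fh:
        fh.write("haplotype_id\tsequence\ttotal_count")
        for p in pops:
            fh.write(f"\t{p}")
        fh.write("\n")
        for h, seq in enumerate(table.haplotype_seqs):
            fh.write(f"H{h + 1}\t{seq}\t{totals[h]}")
            for p in pops:
                fh.write(f"\t{table.counts_by_population[p][h]}")
            fh.write("\n")


def write_haplotype_assignment(table: HaplotypeTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\thaplotype_id\n")
        for sid, h in table.assignment.items():
            fh.write(f"{sid}\tH{h + 1}\n")


def alignment_to_fasta_string(aln: Alignment) -> str:
    buf = io.StringIO()
    records = [
        SeqRecord(Seq(seq), id=sid, description="")
        for sid, seq in zip(aln.sample_ids, aln.sequences())
    ]
    SeqIO.write(records, buf, "fasta-2line")
    return buf.getvalue()
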