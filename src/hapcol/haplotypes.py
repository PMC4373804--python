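"""Alignment input, trimming, and haplotype collapsing.

This module turns an aligned set of mitochondrial sequences (plus a sample
metadata table) into a :class:`HaplotypeTable`: the distinct sequence
variants observed in the ingroup, with per-island (and optionally
per-population) sample counts.  The haplotype x island incidence structure
is the substrate for both the haplotype network and the colonization
metrics.

Sequence-free tables (read from an incidence matrix with
:func:`read_incidence`) are supported for metric-only analyses; operations
that need the actual sequences refuse them explicitly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

from .errors import (AlignmentError, EmptyResultError, InputError,
                     UnsupportedOperationError)

# Nucleotide alphabet: canonical bases, IUPAC ambiguity codes, gap, N.
CANONICAL_BASES = frozenset("ACGT")
IUPAC_AMBIGUITY = frozenset("RYSWKMBDHVN")
ALLOWED_CHARS = CANONICAL_BASES | IUPAC_AMBIGUITY | frozenset("-")

#: IUPAC code -> set of canonical bases it may stand for.
IUPAC_SETS: Mapping[str, frozenset] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"), "-": frozenset(),
}

METADATA_COLUMNS = ("sample_id", "island", "population", "species",
                    "is_outgroup")

#: Islands merged before counting; Baltra and Santa Cruz shared a recent
#: land bridge and are treated as a single island.
DEFAULT_ISLAND_ALIASES: Mapping[str, str] = {"Baltra": "Santa Cruz"}

AMBIGUITY_POLICIES = ("exclude", "collapse-compatible")


def _normalize_sequence(seq: str) -> str:
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class Alignment:
    """Equal-length nucleotide sequences keyed by unique sample ids.

    Input order of records is preserved; it determines haplotype numbering
    downstream (first-occurrence rule).
    """

    records: tuple  # tuple of (sample_id, sequence)

    def __post_init__(self):
        if not self.records:
            raise InputError("alignment contains no records")
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) != 1:
            raise AlignmentError(
                f"sequences have unequal lengths: {sorted(lengths)}"
            )
        ids = [sid for sid, _ in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({s for s in ids if ids.count(s) > 1})
            raise InputError(f"duplicate sample ids: {dupes}")
        for sid, seq in self.records:
            bad = set(seq) - ALLOWED_CHARS
            if bad:
                raise InputError(
                    f"illegal characters {sorted(bad)} in sample {sid!r}"
                )

    @property
    def length(self) -> int:
        return len(self.records[0][1])

    @property
    def sample_ids(self) -> tuple:
        return tuple(sid for sid, _ in self.records)

    def __len__(self) -> int:
        return len(self.records)


def read_alignment(path) -> Alignment:
    """Read a FASTA file (wrapped or single-line) into an :class:`Alignment`.

    Sequences are uppercased and RNA ``U`` is mapped to ``T``.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"alignment file not found: {path}")
    records = [
        (rec.id, _normalize_sequence(str(rec.seq)))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise InputError(f"no FASTA records in {path}")
    return Alignment(records=tuple(records))


def write_alignment(aln: Alignment, path) -> None:
    """Write an alignment as single-line-per-sequence FASTA."""
    with open(path, "w") as fh:
        for sid, seq in aln.records:
            fh.write(f">{sid}\n{seq}\n")


def trim_alignment(aln: Alignment, drop_leading: int = 0,
                   drop_trailing: int = 0) -> Alignment:
    """Drop low-quality flanks, keeping the central analysis window.

    A 279 bp fragment trimmed by 62 leading positions leaves the 217 bp
    window analysed downstream.
    """
    if drop_leading < 0 or drop_trailing < 0:
        raise InputError("trim amounts must be non-negative")
    if drop_leading + drop_trailing >= aln.length:
        raise InputError(
            f"trim window empty: drop {drop_leading}+{drop_trailing} "
            f"from length {aln.length}"
        )
    if drop_leading == 0 and drop_trailing == 0:
        return aln
    stop = aln.length - drop_trailing
    return Alignment(records=tuple(
        (sid, seq[drop_leading:stop]) for sid, seq in aln.records
    ))


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in ("1", "true", "yes", "t", "y"):
        return True
    if text in ("0", "false", "no", "f", "n", ""):
        return False
    raise InputError(f"cannot interpret {value!r} as a boolean outgroup flag")


def read_metadata(path, island_aliases: Mapping[str, str] | None = None,
                  islands: Iterable[str] | None = None) -> pd.DataFrame:
    """Read the sample metadata TSV.

    Required columns: sample_id, island, population, species, is_outgroup.
    Island aliases (default merges Baltra into Santa Cruz) are resolved
    here, before any counting.  If ``islands`` is given, resolved island
    names must be drawn from it.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"metadata file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"metadata missing columns: {sorted(missing)}")
    return prepare_metadata(df, island_aliases=island_aliases, islands=islands)


def prepare_metadata(df: pd.DataFrame,
                     island_aliases: Mapping[str, str] | None = None,
                     islands: Iterable[str] | None = None) -> pd.DataFrame:
    """Validate and normalize a metadata frame (alias resolution, NFC/strip
    of island names, boolean outgroup flags)."""
    import unicodedata

    aliases = DEFAULT_ISLAND_ALIASES if island_aliases is None else island_aliases
    df = df.copy()
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"metadata missing columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dupes = sorted(df.loc[df["sample_id"].duplicated(), "sample_id"])
        raise InputError(f"duplicate metadata rows for samples: {dupes}")

    def norm_island(name):
        name = unicodedata.normalize("NFC", str(name).strip())
        return aliases.get(name, name)

    df["island"] = df["island"].map(norm_island)
    df["is_outgroup"] = df["is_outgroup"].map(_parse_bool)
    if islands is not None:
        allowed = {unicodedata.normalize("NFC", i) for i in islands}
        unknown = sorted(
            set(df.loc[~df["is_outgroup"], "island"]) - allowed)
        if unknown:
            raise InputError(
                f"islands not in declared archipelago list: {unknown}")
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Haplotype table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Haplotype:
    haplotype_id: str
    sequence: str | None  # None in sequence-free (incidence-only) mode


@dataclass
class HaplotypeTable:
    """Distinct haplotypes with per-island sample counts.

    ``haplotypes`` are the ingroup variants; outgroup haplotypes (used only
    to orient ancestrality) are kept separately and carry no island counts.
    ``counts`` is a haplotype x island integer matrix whose grand total is
    the number of ingroup samples retained.
    """

    haplotypes: tuple  # tuple of Haplotype (ingroup)
    counts: pd.DataFrame  # index haplotype_id, columns island names
    outgroup_haplotypes: tuple = ()
    population_counts: pd.DataFrame | None = None

    def __post_init__(self):
        ids = [h.haplotype_id for h in self.haplotypes]
        if list(self.counts.index) != ids:
            raise InputError("counts index does not match haplotype ids")
        if (self.counts.values < 0).any():
            raise InputError("negative counts")
        totals = self.counts.sum(axis=1)
        if (totals < 1).any():
            empty = sorted(totals[totals < 1].index)
            raise InputError(f"haplotypes with zero samples: {empty}")
        seqs = [h.sequence for h in self.haplotypes if h.sequence is not None]
        if len(set(seqs)) != len(seqs):
            raise InputError("haplotype sequences are not pairwise distinct")

    @property
    def has_sequences(self) -> bool:
        return all(h.sequence is not None for h in self.haplotypes)

    @property
    def haplotype_ids(self) -> tuple:
        return tuple(h.haplotype_id for h in self.haplotypes)

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    @property
    def islands(self) -> tuple:
        return tuple(self.counts.columns)

    @property
    def total_samples(self) -> int:
        return int(self.counts.values.sum())

    def sequence_of(self, haplotype_id: str) -> str:
        for h in self.haplotypes + self.outgroup_haplotypes:
            if h.haplotype_id == haplotype_id:
                if h.sequence is None:
                    raise UnsupportedOperationError(
                        f"haplotype {haplotype_id!r} carries no sequence "
                        f"(incidence-only table)")
                return h.sequence
        raise InputError(f"unknown haplotype id {haplotype_id!r}")

    def island_sets(self) -> dict:
        """haplotype_id -> frozenset of islands where its count is > 0."""
        return {
            hid: frozenset(self.counts.columns[self.counts.loc[hid] > 0])
            for hid in self.counts.index
        }

    def sample_counts(self) -> dict:
        """haplotype_id -> total number of samples carrying it."""
        return {hid: int(v) for hid, v in self.counts.sum(axis=1).items()}

    # -- writers ------------------------------------------------------------

    def write_incidence(self, path) -> None:
        """Write the haplotype x island count matrix as TSV."""
        out = self.counts.copy()
        out.index.name = "haplotype"
        out.to_csv(path, sep="\t")

    def write_tsv(self, path) -> None:
        """Write the full table (id, sequence, total, per-island counts)."""
        rows = []
        for h in self.outgroup_haplotypes:
            rows.append({"haplotype": h.haplotype_id,
                         "sequence": h.sequence or "",
                         "is_outgroup": 1, "total": 0,
                         **{i: 0 for i in self.counts.columns}})
        for h in self.haplotypes:
            counts = self.counts.loc[h.haplotype_id]
            rows.append({"haplotype": h.haplotype_id,
                         "sequence": h.sequence or "",
                         "is_outgroup": 0,
                         "total": int(counts.sum()),
                         **{i: int(counts[i]) for i in self.counts.columns}})
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    def to_json(self) -> str:
        payload = {
            "haplotypes": [
                {"haplotype_id": h.haplotype_id, "sequence": h.sequence,
                 "counts": {i: int(self.counts.loc[h.haplotype_id, i])
                            for i in self.counts.columns
                            if self.counts.loc[h.haplotype_id, i] > 0}}
                for h in self.haplotypes
            ],
            "outgroup_haplotypes": [
                {"haplotype_id": h.haplotype_id, "sequence": h.sequence}
                for h in self.outgroup_haplotypes
            ],
            "islands": list(self.counts.columns),
            "total_samples": self.total_samples,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _is_unambiguous(seq: str) -> bool:
    return set(seq) <= CANONICAL_BASES


def _compatible(ambig: str, plain: str) -> bool:
    """True if `ambig` matches `plain` at every unambiguous position and
    every ambiguity code of `ambig` allows the corresponding plain base."""
    return all(p in IUPAC_SETS[a] for a, p in zip(ambig, plain))


def collapse_haplotypes(aln: Alignment, meta: pd.DataFrame,
                        ambiguity_policy: str = "exclude") -> HaplotypeTable:
    """Collapse identical sequences into haplotypes with island counts.

    Numbering is presentational only: distinct outgroup sequences first
    (h1, h2, ...) in first-occurrence order, then ingroup haplotypes in
    first-occurrence order.  Two ambiguity policies are provided:

    ``exclude``
        drop any ingroup sequence containing a non-ACGT character
        (ambiguity code, N or gap); the default.
    ``collapse-compatible``
        merge an ambiguous sequence into the unique unambiguous haplotype
        it is compatible with; if zero or several haplotypes match, the
        sequence is excluded with a warning.
    """
    if ambiguity_policy not in AMBIGUITY_POLICIES:
        raise InputError(f"unknown ambiguity policy {ambiguity_policy!r}")
    meta_idx = meta.set_index("sample_id")
    missing = [sid for sid in aln.sample_ids if sid not in meta_idx.index]
    if missing:
        raise InputError(f"samples without metadata: {missing}")

    outgroup_seqs: list[str] = []
    ingroup: list[tuple[str, str, str, str]] = []  # (sample, seq, island, pop)
    ambiguous: list[tuple[str, str, str, str]] = []
    for sid, seq in aln.records:
        row = meta_idx.loc[sid]
        if row["is_outgroup"]:
            if seq not in outgroup_seqs:
                outgroup_seqs.append(seq)
            continue
        if _is_unambiguous(seq):
            ingroup.append((sid, seq, row["island"], row["population"]))
        elif ambiguity_policy == "collapse-compatible":
            ambiguous.append((sid, seq, row["island"], row["population"]))
        else:
            warnings.warn(
                f"sample {sid!r} excluded (ambiguous characters, "
                f"policy=exclude)", stacklevel=2)

    hap_seqs: list[str] = []
    assignments: list[tuple[str, str, str]] = []  # (seq, island, population)
    for sid, seq, island, pop in ingroup:
        if seq not in hap_seqs:
            hap_seqs.append(seq)
        assignments.append((seq, island, pop))

    for sid, seq, island, pop in ambiguous:
        matches = [h for h in hap_seqs if _compatible(seq, h)]
        if len(matches) == 1:
            assignments.append((matches[0], island, pop))
        else:
            why = "no compatible haplotype" if not matches else \
                f"{len(matches)} compatible haplotypes (tie)"
            warnings.warn(
                f"sample {sid!r} excluded under collapse-compatible: {why}",
                stacklevel=2)

    if not assignments:
        raise EmptyResultError(
            "no ingroup samples left after ambiguity filtering")

    n_out = len(outgroup_seqs)
    outgroup = tuple(
        Haplotype(f"h{i + 1}", seq) for i, seq in enumerate(outgroup_seqs))
    haplotypes = tuple(
        Haplotype(f"h{n_out + i + 1}", seq) for i, seq in enumerate(hap_seqs))
    hap_id_of = {h.sequence: h.haplotype_id for h in haplotypes}

    islands = sorted({a[1] for a in assignments})
    counts = pd.DataFrame(
        0, index=[h.haplotype_id for h in haplotypes], columns=islands,
        dtype=int)
    populations = sorted({a[2] for a in assignments})
    pop_counts = pd.DataFrame(
        0, index=[h.haplotype_id for h in haplotypes], columns=populations,
        dtype=int)
    for seq, island, pop in assignments:
        hid = hap_id_of[seq]
        counts.loc[hid, island] += 1
        pop_counts.loc[hid, pop] += 1

    return HaplotypeTable(haplotypes=haplotypes, counts=counts,
                          outgroup_haplotypes=outgroup,
                          population_counts=pop_counts)


# ---------------------------------------------------------------------------
# Incidence-matrix entry point (sequence-free mode)
# ---------------------------------------------------------------------------

def read_incidence(path) -> HaplotypeTable:
    """Read a haplotype x island incidence (count) matrix TSV.

    Header row holds island names; first column holds haplotype ids.
    Cells must be non-negative integers.  The resulting table carries no
    sequences; sequence-dependent operations refuse it.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"incidence file not found: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.empty:
        raise InputError(f"incidence matrix {path} has no rows")
    for col in df.columns:
        vals = df[col]
        numeric = pd.to_numeric(vals, errors="coerce")
        if numeric.isna().any() or (numeric % 1 != 0).any():
            raise InputError(f"non-integer cell in column {col!r}")
        if (numeric < 0).any():
            raise InputError(f"negative cell in column {col!r}")
        df[col] = numeric.astype(int)
    haplotypes = tuple(Haplotype(str(hid), None) for hid in df.index)
    df.index = [str(i) for i in df.index]
    return HaplotypeTable(haplotypes=haplotypes, counts=df)


def read_haplotype_table(path) -> HaplotypeTable:
    """Read back a table written by :meth:`HaplotypeTable.write_tsv`."""
    df = pd.read_csv(Path(path), sep="\t", dtype={"haplotype": str,
                                                  "sequence": str})
    df["sequence"] = df["sequence"].fillna("")
    needed = {"haplotype", "sequence", "is_outgroup", "total"}
    if not needed <= set(df.columns):
        raise InputError(f"haplotype table missing columns "
                         f"{sorted(needed - set(df.columns))}")
    island_cols = [c for c in df.columns if c not in needed]
    out_rows = df[df["is_outgroup"] == 1]
    in_rows = df[df["is_outgroup"] == 0]
    outgroup = tuple(
        Haplotype(r["haplotype"], r["sequence"] or None)
        for _, r in out_rows.iterrows())
    haplotypes = tuple(
        Haplotype(r["haplotype"], r["sequence"] or None)
        for _, r in in_rows.iterrows())
    counts = in_rows.set_index("haplotype")[island_cols].astype(int)
    counts.index.name = None
    return HaplotypeTable(haplotypes=haplotypes, counts=counts,
                          outgroup_haplotypes=outgroup)
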