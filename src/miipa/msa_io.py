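"""Read, validate, filter, and subsample species-annotated paired alignments.

The pairing problem starts from two fixed-width multiple sequence alignments,
one per protein family (A and B), in which every record carries a species
label.  Partner prediction is a within-species assignment problem: each A
paralog must be matched to exactly one B paralog of the same species.  This
module provides the alignment container, FASTA/TSV input and output, the
standard dataset filters (drop species with fewer than two pairs, balance
unequal family counts by the minimum), and whole-species subsampling.

Residues are encoded as integer states 0..20: the twenty amino acids in
alphabetical one-letter order followed by the gap state.  All user-facing
coordinates (site indices in reports) are 1-based; internal arrays are
0-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Amino-acid alphabet; index = state code. The gap '-' is state 20.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP_STATE = 20
N_STATES = 21

#: Letters outside the 20-residue alphabet that are mapped to the gap state.
NONSTANDARD = set("BZXUOJ")

_CODE = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_CODE["-"] = GAP_STATE
_CODE["."] = GAP_STATE
_DECODE = AMINO_ACIDS + "-"


def encode_sequence(seq: str) -> tuple[np.ndarray, int]:
    """Encode one aligned sequence as uint8 state codes.

    Returns the code vector and the number of non-standard letters that were
    mapped to the gap state.
    """
    out = np.empty(len(seq), dtype=np.uint8)
    n_nonstandard = 0
    for k, ch in enumerate(seq.upper()):
        code = _CODE.get(ch)
        if code is None:
            if ch in NONSTANDARD:
                n_nonstandard += 1
                code = GAP_STATE
            else:
                raise ValueError(f"unknown residue letter {ch!r} at column {k + 1}")
        out[k] = code
    return out, n_nonstandard


def decode_sequence(row: np.ndarray) -> str:
    """Inverse of :func:`encode_sequence` (non-standard letters become '-')."""
    return "".join(_DECODE[c] for c in row)


def parse_header_pipe(description: str) -> tuple[str, str]:
    """Default header dialect ``>id|species``."""
    fields = description.split()[0].split("|")
    if len(fields) < 2 or not fields[0] or not fields[1]:
        raise ValueError(f"header {description!r} does not match 'id|species'")
    return fields[0], fields[1]


@dataclass
class PairedAlignment:
    """Two species-annotated alignment blocks plus an optional gold pairing.

    ``gold`` maps A-record ids to their true B partner id (when known from,
    e.g., genome adjacency); it is used only for benchmarking, never by the
    pairing algorithm itself.
    """

    ids_a: list[str]
    species_a: list[str]
    X_a: np.ndarray  # (N_A, L_A) uint8 state codes
    ids_b: list[str]
    species_b: list[str]
    X_b: np.ndarray  # (N_B, L_B)
    gold: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.X_a = np.asarray(self.X_a, dtype=np.uint8)
        self.X_b = np.asarray(self.X_b, dtype=np.uint8)
        if self.X_a.ndim != 2 or self.X_b.ndim != 2:
            raise ValueError("alignment blocks must be 2-D")
        if len(self.ids_a) != self.X_a.shape[0] or len(self.ids_b) != self.X_b.shape[0]:
            raise ValueError("id list and alignment block disagree in length")
        if len(set(self.ids_a)) != len(self.ids_a) or len(set(self.ids_b)) != len(self.ids_b):
            raise ValueError("duplicate record ids")
        for X in (self.X_a, self.X_b):
            if X.size and X.max() >= N_STATES:
                raise ValueError("state codes must lie in 0..20")

    # -- geometry -----------------------------------------------------------
    @property
    def L_a(self) -> int:
        return self.X_a.shape[1]

    @property
    def L_b(self) -> int:
        return self.X_b.shape[1]

    @property
    def L(self) -> int:
        return self.L_a + self.L_b

    @property
    def species_index(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """species -> (A row indices, B row indices), in file order."""
        idx: dict[str, tuple[list[int], list[int]]] = {}
        for i, sp in enumerate(self.species_a):
            idx.setdefault(sp, ([], []))[0].append(i)
        for i, sp in enumerate(self.species_b):
            idx.setdefault(sp, ([], []))[1].append(i)
        return {
            sp: (np.array(a, dtype=int), np.array(b, dtype=int))
            for sp, (a, b) in idx.items()
        }

    @property
    def M(self) -> int:
        """Number of matchable pairs: sum over species of min(#A, #B)."""
        return sum(min(len(a), len(b)) for a, b in self.species_index.values())

    @property
    def n_species(self) -> int:
        return len(self.species_index)

    def is_balanced(self) -> bool:
        return all(len(a) == len(b) for a, b in self.species_index.values())

    @property
    def index_a(self) -> dict[str, int]:
        return {rid: i for i, rid in enumerate(self.ids_a)}

    @property
    def index_b(self) -> dict[str, int]:
        return {rid: i for i, rid in enumerate(self.ids_b)}


@dataclass
class ConcatenatedAlignment:
    """Concatenated A+B rows for a candidate set of within-species pairs."""

    rows: np.ndarray  # (M_ca, L_a + L_b) uint8
    a_indices: np.ndarray  # rows into the parent alignment's A block
    b_indices: np.ndarray
    L_a: int

    @property
    def M(self) -> int:
        return self.rows.shape[0]

    @property
    def L(self) -> int:
        return self.rows.shape[1]


def build_ca(aln: PairedAlignment, pairs: Sequence[tuple[int, int]]) -> ConcatenatedAlignment:
    """Concatenate A and B rows for the given (A index, B index) pairs."""
    if len(pairs) == 0:
        raise ValueError("cannot build an empty concatenated alignment")
    ai = np.array([p[0] for p in pairs], dtype=int)
    bi = np.array([p[1] for p in pairs], dtype=int)
    rows = np.concatenate([aln.X_a[ai], aln.X_b[bi]], axis=1)
    return ConcatenatedAlignment(rows=rows, a_indices=ai, b_indices=bi, L_a=aln.L_a)


# ---------------------------------------------------------------------------
# FASTA / TSV I/O
# ---------------------------------------------------------------------------

def _read_family(path: Path, species_parser, species_table: dict[str, str] | None):
    ids: list[str] = []
    species: list[str] = []
    rows: list[np.ndarray] = []
    n_nonstandard = 0
    width = None
    for k, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        if species_table is not None:
            rid = rec.id
            try:
                sp = species_table[rid]
            except KeyError:
                raise ValueError(f"record {k} ({rid!r}) in {path} has no species entry")
        else:
            try:
                rid, sp = species_parser(rec.description)
            except ValueError as exc:
                raise ValueError(f"record {k} in {path}: {exc}") from exc
        try:
            row, bad = encode_sequence(str(rec.seq))
        except ValueError as exc:
            raise ValueError(f"record {k} ({rid!r}) in {path}: {exc}") from exc
        if width is None:
            width = row.size
        elif row.size != width:
            raise ValueError(
                f"ragged alignment in {path}: record {k} ({rid!r}) has width "
                f"{row.size}, expected {width}"
            )
        n_nonstandard += bad
        ids.append(rid)
        species.append(sp)
        rows.append(row)
    if not rows:
        raise ValueError(f"no records in {path}")
    if n_nonstandard:
        logger.warning(
            "%s: %d non-standard residue letters mapped to the gap state",
            path, n_nonstandard,
        )
    return ids, species, np.vstack(rows)


def read_paired_fasta(
    fasta_a: str | Path,
    fasta_b: str | Path,
    species_parser: Callable[[str], tuple[str, str]] = parse_header_pipe,
    species_table: str | Path | None = None,
    gold_table: str | Path | None = None,
) -> PairedAlignment:
    """Read the two family alignments into a :class:`PairedAlignment`.

    ``species_parser`` extracts (id, species) from a FASTA header; the default
    dialect is ``>id|species``.  Alternatively ``species_table`` names a
    two-column TSV (id, species) covering both families.  ``gold_table``
    optionally names a pairing TSV (columns species, id_A, id_B) giving the
    true partners.
    """
    table = None
    if species_table is not None:
        df = pd.read_csv(species_table, sep="\t", header=None, names=["id", "species"], dtype=str)
        table = dict(zip(df["id"], df["species"]))
        species_parser = lambda desc: (desc.split()[0], "")  # id only  # noqa: E731
    ids_a, sp_a, X_a = _read_family(Path(fasta_a), species_parser, table)
    ids_b, sp_b, X_b = _read_family(Path(fasta_b), species_parser, table)
    gold = None
    if gold_table is not None:
        gold = {row.id_A: row.id_B for row in read_pairing_table(gold_table).itertuples()}
    return PairedAlignment(ids_a, sp_a, X_a, ids_b, sp_b, X_b, gold=gold)


def write_paired_fasta(aln: PairedAlignment, fasta_a: str | Path, fasta_b: str | Path) -> None:
    """Write both family blocks back to FASTA using the ``id|species`` dialect."""
    for path, ids, species, X in (
        (fasta_a, aln.ids_a, aln.species_a, aln.X_a),
        (fasta_b, aln.ids_b, aln.species_b, aln.X_b),
    ):
        with open(path, "w") as fh:
            for rid, sp, row in zip(ids, species, X):
                fh.write(f">{rid}|{sp}\n{decode_sequence(row)}\n")


def read_pairing_table(path: str | Path) -> pd.DataFrame:
    """Read a pairing TSV with columns (species, id_A, id_B)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"species", "id_A", "id_B"} - set(df.columns)
    if missing:
        raise ValueError(f"pairing table {path} lacks columns {sorted(missing)}")
    return df


def write_pairing_table(
    path: str | Path, rows: Iterable[tuple[str, str, str]]
) -> None:
    """Write (species, id_A, id_B) triples as a TSV pairing table."""
    df = pd.DataFrame(rows, columns=["species", "id_A", "id_B"])
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def filter_and_balance(aln: PairedAlignment, min_pairs: int = 2) -> PairedAlignment:
    """Apply the standard dataset filter and balance family counts.

    Species with fewer than ``min_pairs`` matchable pairs are discarded (a
    single pair carries no ambiguity and would act as an implicit training
    pair).  Within each retained species the two families are balanced to
    min(#A, #B) records by dropping the records with the largest file-order
    index from the larger family, which keeps the operation deterministic.
    """
    keep_a: list[int] = []
    keep_b: list[int] = []
    for sp in sorted(aln.species_index):
        ia, ib = aln.species_index[sp]
        m = min(len(ia), len(ib))
        if m < min_pairs:
            continue
        keep_a.extend(ia[:m])
        keep_b.extend(ib[:m])
    if not keep_a:
        raise ValueError("no species left after filtering")
    keep_a.sort()
    keep_b.sort()
    ids_a = [aln.ids_a[i] for i in keep_a]
    ids_b = [aln.ids_b[i] for i in keep_b]
    gold = None
    if aln.gold is not None:
        bset = set(ids_b)
        gold = {a: b for a, b in aln.gold.items() if a in set(ids_a) and b in bset}
    return PairedAlignment(
        ids_a=ids_a,
        species_a=[aln.species_a[i] for i in keep_a],
        X_a=aln.X_a[keep_a],
        ids_b=ids_b,
        species_b=[aln.species_b[i] for i in keep_b],
        X_b=aln.X_b[keep_b],
        gold=gold,
    )


def subsample_by_species(
    aln: PairedAlignment, target_M: int, rng: int | np.random.Generator
) -> PairedAlignment:
    """Draw whole species in random order until >= ``target_M`` pairs are kept.

    Mirrors how reduced-size benchmark datasets are constructed: species are
    picked at random from the full dataset, so within-species structure is
    preserved.  The gold pairing (restricted to retained records) survives.
    """
    rng = np.random.default_rng(rng)
    index = aln.species_index
    sizes = {sp: min(len(a), len(b)) for sp, (a, b) in index.items()}
    if target_M > aln.M:
        raise ValueError(f"target_M={target_M} exceeds available pairs M={aln.M}")
    if target_M < min(sizes.values()):
        raise ValueError(
            f"target_M={target_M} is below the smallest species size "
            f"{min(sizes.values())}; no species subset can stop at it"
        )
    order = sorted(index)
    rng.shuffle(order)
    chosen: list[str] = []
    total = 0
    for sp in order:
        chosen.append(sp)
        total += sizes[sp]
        if total >= target_M:
            break
    chosen_set = set(chosen)
    keep_a = [i for i, sp in enumerate(aln.species_a) if sp in chosen_set]
    keep_b = [i for i, sp in enumerate(aln.species_b) if sp in chosen_set]
    ids_a = [aln.ids_a[i] for i in keep_a]
    ids_b = [aln.ids_b[i] for i in keep_b]
    gold = None
    if aln.gold is not None:
        bset = set(ids_b)
        gold = {a: b for a, b in aln.gold.items() if a in set(ids_a) and b in bset}
    return PairedAlignment(
        ids_a=ids_a,
        species_a=[aln.species_a[i] for i in keep_a],
        X_a=aln.X_a[keep_a],
        ids_b=ids_b,
        species_b=[aln.species_b[i] for i in keep_b],
        X_b=aln.X_b[keep_b],
        gold=gold,
    )


def describe(aln: PairedAlignment) -> dict:
    """Dataset descriptives: pair/species counts, mean pairs per species, widths."""
    sizes = [min(len(a), len(b)) for a, b in aln.species_index.values()]
    return {
        "n_pairs": int(sum(sizes)),
        "n_species": len(sizes),
        "mean_pairs_per_species": float(np.mean(sizes)) if sizes else 0.0,
        "L_A": aln.L_a,
        "L_B": aln.L_b,
    }
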