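"""Feature encoders: one-hot, physicochemical, composition and positional preference.

Two encoder groups feed the dual-input model. The single-residue group
(one-hot, phychem) encodes the zero-padded concatenated pair, peptide
block first (11 rows) then CDR3 block (21 rows), 32 rows total. The
distribution group encodes either per-sequence residue composition (AAC)
or, per peptide, the positional residue preference of its cognate TCR
repertoire (AAPP) over CDR3 positions 2..21.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from itcep.alphabet import (
    AA_INDEX,
    AAPP_POSITIONS,
    AMINO_ACIDS,
    CDR3_MAX_LEN,
    CDR3_MIN_LEN,
    PAIR_ROWS,
    PEPTIDE_MAX_LEN,
    PEPTIDE_MIN_LEN,
    is_valid_sequence,
)
from itcep.io_data import PairRecord
from itcep.nearest_peptide import nearest_training_peptide

__all__ = [
    "FeatureMap",
    "AACVector",
    "AAPPTable",
    "PhychemTable",
    "FusedFeatures",
    "FUSION_SCHEMES",
    "encode_onehot_pair",
    "encode_phychem_pair",
    "compute_aac",
    "build_aapp_table",
    "lookup_aapp",
    "fuse_pair",
    "load_phychem_table",
]

FUSION_SCHEMES = ("onehot-aac", "onehot-aapp", "phychem-aac", "phychem-aapp")


@dataclass(frozen=True)
class FeatureMap:
    """A 2-D numeric feature matrix tagged with the encoder that produced it."""

    values: np.ndarray
    kind: str  # one of {"onehot", "phychem", "aac", "aapp"}

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def n_entries(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class AACVector:
    """Per-residue occurrence frequencies of one sequence (sums to 1)."""

    frequencies: np.ndarray

    def __post_init__(self) -> None:
        assert self.frequencies.shape == (20,)


@dataclass(frozen=True)
class FusedFeatures:
    module1_map: FeatureMap
    module2_map: FeatureMap
    scheme: str


def _check_pair(peptide: str, cdr3: str) -> None:
    if not is_valid_sequence(peptide) or not is_valid_sequence(cdr3):
        raise ValueError("sequences must use the 20 canonical amino-acid letters")
    if not (PEPTIDE_MIN_LEN <= len(peptide) <= PEPTIDE_MAX_LEN):
        raise ValueError(f"peptide length {len(peptide)} outside [{PEPTIDE_MIN_LEN}, {PEPTIDE_MAX_LEN}]")
    if not (CDR3_MIN_LEN <= len(cdr3) <= CDR3_MAX_LEN):
        raise ValueError(f"CDR3 length {len(cdr3)} outside [{CDR3_MIN_LEN}, {CDR3_MAX_LEN}]")


def _onehot_block(seq: str, n_rows: int) -> np.ndarray:
    block = np.zeros((n_rows, 20), dtype=np.float64)
    for r, aa in enumerate(seq):
        block[r, AA_INDEX[aa]] = 1.0
    return block


def encode_onehot_pair(peptide: str, cdr3: str) -> FeatureMap:
    """One-hot encode the pair as an 11+21 = 32 row x 20 column binary map.

    Each sequence is right-zero-padded to its block height (peptide 11,
    CDR3 21); the peptide block is stacked above the CDR3 block. The map
    contains exactly len(peptide) + len(cdr3) ones.
    """
    _check_pair(peptide, cdr3)
    values = np.vstack(
        [_onehot_block(peptide, PEPTIDE_MAX_LEN), _onehot_block(cdr3, CDR3_MAX_LEN)]
    )
    assert values.shape == (PAIR_ROWS, 20)
    return FeatureMap(values=values, kind="onehot")


class PhychemTable:
    """Per-residue values for 21 named physicochemical scales, standardized.

    Each scale is standardized to mean 0, variance 1 over the 20 canonical
    residues, fixed once at load time (not refit per dataset). The default
    table ships with the package and can be replaced via a CSV with a
    ``residue`` column and one column per scale.
    """

    def __init__(self, raw: pd.DataFrame):
        if list(raw.index) != list(AMINO_ACIDS):
            raw = raw.loc[list(AMINO_ACIDS)]
        self.scale_names: list[str] = list(raw.columns)
        values = raw.to_numpy(dtype=np.float64)
        self.means = values.mean(axis=0)
        # Population variance over the 20 residues.
        self.stds = values.std(axis=0)
        if np.any(self.stds == 0):
            bad = [n for n, s in zip(self.scale_names, self.stds) if s == 0]
            raise ValueError(f"constant scales cannot be standardized: {bad}")
        self.values = (values - self.means) / self.stds

    @property
    def n_scales(self) -> int:
        return len(self.scale_names)

    def row(self, residue: str) -> np.ndarray:
        try:
            return self.values[AA_INDEX[residue]]
        except KeyError:
            raise KeyError(f"residue {residue!r} not in table") from None


def load_phychem_table(path: str | Path | None = None) -> PhychemTable:
    """Load the default (or a user-supplied) physicochemical scales CSV."""
    if path is None:
        ref = resources.files("itcep.data").joinpath("phychem_scales.csv")
        with resources.as_file(ref) as p:
            raw = pd.read_csv(p, index_col="residue")
    else:
        raw = pd.read_csv(path, index_col="residue")
    return PhychemTable(raw)


def encode_phychem_pair(peptide: str, cdr3: str, table: PhychemTable) -> FeatureMap:
    """Encode the pair as a 32-row map whose row r holds the standardized
    scale values of the residue at that position; padding rows are zero."""
    _check_pair(peptide, cdr3)
    values = np.zeros((PAIR_ROWS, table.n_scales), dtype=np.float64)
    for r, aa in enumerate(peptide):
        values[r] = table.row(aa)
    for r, aa in enumerate(cdr3):
        values[PEPTIDE_MAX_LEN + r] = table.row(aa)
    return FeatureMap(values=values, kind="phychem")


def compute_aac(sequence: str) -> AACVector:
    """Amino-acid composition: per-residue count divided by sequence length."""
    if not sequence:
        raise ValueError("sequence must be non-empty")
    if not is_valid_sequence(sequence):
        raise ValueError("sequence contains non-canonical residues")
    counts = np.zeros(20, dtype=np.float64)
    for aa in sequence:
        counts[AA_INDEX[aa]] += 1.0
    return AACVector(frequencies=counts / len(sequence))


class AAPPTable:
    """Per-peptide positional residue probabilities of the cognate TCR repertoire.

    For each unique peptide p with N_t cognate CDR3s, entry (x, i) is the
    number of cognate CDR3s carrying residue i at 1-based position x,
    divided by N_t, for x = 2..21 (position 1, the shared start cysteine,
    is excluded). Stored transposed: rows are the 20 positions, columns
    the 20 residues, so each map is 20 x 20 = 400 entries.
    """

    def __init__(self, maps: Mapping[str, np.ndarray], tcr_counts: Mapping[str, int]):
        for pep, m in maps.items():
            if m.shape != (AAPP_POSITIONS, 20):
                raise ValueError(f"map for {pep!r} has shape {m.shape}, expected (20, 20)")
        self.maps: dict[str, np.ndarray] = dict(maps)
        self.tcr_counts: dict[str, int] = dict(tcr_counts)

    @property
    def peptides(self) -> list[str]:
        return list(self.maps)

    def __len__(self) -> int:
        return len(self.maps)

    def __contains__(self, peptide: str) -> bool:
        return peptide in self.maps

    def save(self, path: str | Path) -> None:
        """Serialize to JSON (one 20x20 matrix per peptide), round-trip exact."""
        payload = {
            "positions": AAPP_POSITIONS,
            "residue_order": AMINO_ACIDS,
            "tcr_counts": self.tcr_counts,
            "maps": {p: m.tolist() for p, m in self.maps.items()},
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "AAPPTable":
        payload = json.loads(Path(path).read_text())
        if payload["residue_order"] != AMINO_ACIDS:
            raise ValueError("AAPP table was built with a different residue order")
        maps = {p: np.asarray(m, dtype=np.float64) for p, m in payload["maps"].items()}
        return cls(maps=maps, tcr_counts=payload["tcr_counts"])


def build_aapp_table(positive_records: Iterable[PairRecord]) -> AAPPTable:
    """Build per-peptide positional preference maps from positive pairs only."""
    grouped: dict[str, list[str]] = {}
    for rec in positive_records:
        if rec.label != 1:
            raise ValueError("AAPP tables are built from positive (label 1) records only")
        grouped.setdefault(rec.peptide, []).append(rec.cdr3)

    maps: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    for pep, cdr3s in grouped.items():
        n_t = len(cdr3s)
        m = np.zeros((AAPP_POSITIONS, 20), dtype=np.float64)
        for cdr3 in cdr3s:
            # 1-based position x runs 2..21 -> row x-2, residue cdr3[x-1].
            for x in range(2, min(len(cdr3), CDR3_MAX_LEN) + 1):
                m[x - 2, AA_INDEX[cdr3[x - 1]]] += 1.0
        maps[pep] = m / n_t
        counts[pep] = n_t
    return AAPPTable(maps=maps, tcr_counts=counts)


def lookup_aapp(
    peptide: str, table: AAPPTable, training_peptides: Sequence[str] | None = None
) -> FeatureMap:
    """Positional-preference map for ``peptide``; unseen peptides get the
    map of the nearest training peptide under Levenshtein distance."""
    if len(table) == 0:
        raise ValueError("AAPP table is empty")
    if peptide in table:
        return FeatureMap(values=table.maps[peptide].copy(), kind="aapp")
    candidates = training_peptides if training_peptides is not None else table.peptides
    candidates = [c for c in candidates if c in table]
    if not candidates:
        raise ValueError("no training peptides available in the AAPP table")
    result = nearest_training_peptide(peptide, candidates)
    return FeatureMap(values=table.maps[result.match].copy(), kind="aapp")


def fuse_pair(
    peptide: str,
    cdr3: str,
    scheme: str,
    aapp_table: AAPPTable | None = None,
    phychem_table: PhychemTable | None = None,
    training_peptides: Sequence[str] | None = None,
) -> FusedFeatures:
    """Build the two model input maps for one pair under a fusion scheme.

    Module 1 comes from the single-residue group (one-hot or phychem over
    the concatenated pair), module 2 from the distribution group: for AAC
    the peptide and CDR3 composition vectors stacked as a 2x20 matrix, for
    AAPP the peptide's 20x20 positional-preference map (CDR3-independent).
    """
    if scheme not in FUSION_SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {FUSION_SCHEMES}")
    first, second = scheme.split("-")

    if first == "onehot":
        m1 = encode_onehot_pair(peptide, cdr3)
    else:
        if phychem_table is None:
            raise ValueError("phychem scheme requires a PhychemTable")
        m1 = encode_phychem_pair(peptide, cdr3, phychem_table)

    if second == "aac":
        m2 = FeatureMap(
            values=np.vstack(
                [compute_aac(peptide).frequencies, compute_aac(cdr3).frequencies]
            ),
            kind="aac",
        )
    else:
        if aapp_table is None:
            raise ValueError("aapp scheme requires an AAPPTable")
        m2 = lookup_aapp(peptide, aapp_table, training_peptides)

    return FusedFeatures(module1_map=m1, module2_map=m2, scheme=scheme)
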