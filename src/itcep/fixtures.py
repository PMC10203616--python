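"""Synthetic peptide-TCR datasets with planted positional structure.

Every generator is deterministic for a fixed seed, so datasets are never
stored: they regenerate bit-identically from (spec, seed). Each synthetic
epitope gets a cognate CDR3 repertoire whose residues at the anchor
positions follow a peptide-specific preference; a motif-free background
repertoire stands in for healthy-donor sequences used in negative pairing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from itcep.alphabet import AA_INDEX, AMINO_ACIDS
from itcep.io_data import PairRecord, sample_negative_pairs

__all__ = [
    "MotifSpec",
    "generate_epitope_repertoire",
    "generate_background_repertoire",
    "perturb_peptide",
    "make_labeled_dataset",
]


@dataclass(frozen=True)
class MotifSpec:
    """Planted positional preference for cognate CDR3 repertoires.

    ``anchor_positions`` are 1-based CDR3 positions in 2..21. At an anchor,
    a residue is drawn from the preference distribution with probability
    ``strength`` and from the background otherwise; strength 0 reduces to
    background everywhere. When ``position_weights`` is None each peptide
    draws its own preferred residue per anchor, making the positional
    preference epitope-specific.
    """

    anchor_positions: tuple[int, ...] = (3, 4, 5)
    strength: float = 0.9
    position_weights: dict[int, dict[str, float]] | None = None
    background: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError("strength must be in [0, 1]")
        for pos in self.anchor_positions:
            if not 2 <= pos <= 21:
                raise ValueError("anchor positions must lie in 2..21")
        if self.position_weights is not None:
            missing = set(self.anchor_positions) - set(self.position_weights)
            if missing:
                raise ValueError(f"no weights for anchor positions {sorted(missing)}")

    def background_probs(self) -> np.ndarray:
        if self.background is None:
            return np.full(20, 1.0 / 20.0)
        probs = np.zeros(20)
        for aa, w in self.background.items():
            probs[AA_INDEX[aa]] = w
        total = probs.sum()
        if total <= 0:
            raise ValueError("background weights must have positive mass")
        return probs / total

    def anchor_probs(self, position: int) -> np.ndarray | None:
        """Normalized preference distribution at an anchor, or None when
        per-peptide preferences should be drawn."""
        if self.position_weights is None:
            return None
        weights = self.position_weights[position]
        probs = np.zeros(20)
        for aa, w in weights.items():
            probs[AA_INDEX[aa]] = w
        return probs / probs.sum()

    def to_json(self, path: str | Path) -> None:
        payload = {
            "anchor_positions": list(self.anchor_positions),
            "strength": self.strength,
            "position_weights": self.position_weights,
            "background": self.background,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "MotifSpec":
        d = json.loads(Path(path).read_text())
        if d.get("position_weights") is not None:
            d["position_weights"] = {int(k): v for k, v in d["position_weights"].items()}
        return cls(
            anchor_positions=tuple(d["anchor_positions"]),
            strength=d["strength"],
            position_weights=d.get("position_weights"),
            background=d.get("background"),
        )


def _random_sequence(rng: np.random.Generator, length: int, probs: np.ndarray) -> str:
    idx = rng.choice(20, size=length, p=probs)
    return "".join(AMINO_ACIDS[i] for i in idx)


def generate_epitope_repertoire(
    n_peptides: int,
    tcrs_per_peptide: int,
    motif_spec: MotifSpec | None = None,
    peptide_length_range: tuple[int, int] = (8, 11),
    cdr3_length_range: tuple[int, int] = (8, 21),
    seed: int = 0,
) -> list[PairRecord]:
    """Positive pairs: each synthetic peptide with its cognate CDR3 set.

    CDR3s start with C; residues at anchor positions (when within the
    drawn length) follow the peptide's motif with probability
    ``strength``, otherwise background.
    """
    motif_spec = motif_spec or MotifSpec()
    if n_peptides < 1 or tcrs_per_peptide < 1:
        raise ValueError("counts must be >= 1")
    pmin, pmax = peptide_length_range
    cmin, cmax = cdr3_length_range
    if not (8 <= pmin <= pmax <= 11) or not (8 <= cmin <= cmax <= 21):
        raise ValueError("length ranges must fall within curation bounds")

    rng = np.random.default_rng(seed)
    background = motif_spec.background_probs()
    records: list[PairRecord] = []
    peptides: set[str] = set()
    while len(peptides) < n_peptides:
        pep = _random_sequence(rng, int(rng.integers(pmin, pmax + 1)), background)
        peptides.add(pep)
    for pep in sorted(peptides):
        # Per-peptide anchor preferences unless the spec pins them.
        anchor_dists: dict[int, np.ndarray] = {}
        for pos in motif_spec.anchor_positions:
            fixed = motif_spec.anchor_probs(pos)
            if fixed is not None:
                anchor_dists[pos] = fixed
            else:
                onehot = np.zeros(20)
                onehot[int(rng.integers(20))] = 1.0
                anchor_dists[pos] = onehot
        cognate: set[str] = set()
        while len(cognate) < tcrs_per_peptide:
            length = int(rng.integers(cmin, cmax + 1))
            chars = ["C"]
            for pos in range(2, length + 1):
                if pos in anchor_dists and rng.random() < motif_spec.strength:
                    probs = anchor_dists[pos]
                else:
                    probs = background
                chars.append(AMINO_ACIDS[int(rng.choice(20, p=probs))])
            cognate.add("".join(chars))
        records.extend(
            PairRecord(peptide=pep, cdr3=c, label=1, source="synthetic") for c in sorted(cognate)
        )
    return records


def generate_background_repertoire(
    n: int,
    length_range: tuple[int, int] = (8, 21),
    seed: int = 0,
    background: dict[str, float] | None = None,
) -> list[str]:
    """Motif-free CDR3s starting with C, deterministic per seed."""
    if n < 0:
        raise ValueError("n must be nonnegative")
    cmin, cmax = length_range
    if not 8 <= cmin <= cmax <= 21:
        raise ValueError("length range must fall within curation bounds")
    probs = MotifSpec(background=background).background_probs()
    rng = np.random.default_rng(seed)
    out: set[str] = set()
    while len(out) < n:
        length = int(rng.integers(cmin, cmax + 1))
        out.add("C" + _random_sequence(rng, length - 1, probs))
    return sorted(out)


def perturb_peptide(peptide: str, n_edits: int, seed: int = 0) -> str:
    """Substitute ``n_edits`` random positions, producing an unseen-style
    peptide at small edit distance (exercises the nearest-peptide path)."""
    rng = np.random.default_rng(seed)
    chars = list(peptide)
    positions = rng.choice(len(chars), size=min(n_edits, len(chars)), replace=False)
    for pos in positions:
        alternatives = [aa for aa in AMINO_ACIDS if aa != chars[pos]]
        chars[pos] = alternatives[int(rng.integers(19))]
    return "".join(chars)


def make_labeled_dataset(
    n_peptides: int,
    tcrs_per_peptide: int,
    motif_spec: MotifSpec | None = None,
    negative_ratio: float = 1.0,
    seed: int = 0,
) -> tuple[list[PairRecord], list[str]]:
    """Positives with planted motifs plus background-paired negatives.

    Returns (labeled records, background repertoire). The negative pool is
    sized to comfortably cover the requested ratio.
    """
    positives = generate_epitope_repertoire(
        n_peptides, tcrs_per_peptide, motif_spec, seed=seed
    )
    n_neg = int(round(negative_ratio * len(positives)))
    repertoire = generate_background_repertoire(max(n_neg, 100), seed=seed + 1)
    negatives = sample_negative_pairs(
        [r.peptide for r in positives],
        repertoire,
        n_neg,
        seed=seed + 2,
        known_positive_pairs=[r.key() for r in positives],
    )
    return positives + negatives, repertoire
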