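"""Sequence ingestion, charge assignment and charge-pattern statistics.

One bead per residue. Lysine and arginine carry +e, aspartate and
glutamate carry -e, every other residue (including histidine) is
neutral. The module also provides designed-polyampholyte generation
used throughout the test fixtures, and FASTA ingestion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator

import numpy as np
from Bio import SeqIO

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: per-residue charge in units of the elementary charge
RESIDUE_CHARGE = {"K": 1, "R": 1, "D": -1, "E": -1}


@dataclass(frozen=True)
class ChargeSequence:
    """An amino-acid string with its per-residue charge vector."""

    residues: str
    charges: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.residues) != len(self.charges):
            raise ValueError("residues and charges length mismatch")
        object.__setattr__(self, "charges", np.asarray(self.charges, dtype=np.int64))

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def L(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class SequenceMetrics:
    n_pos: int
    n_neg: int
    f_plus: float
    f_minus: float
    ncpr: float
    scd: float


def assign_charges(residues: str) -> ChargeSequence:
    """Build a :class:`ChargeSequence` from a one-letter residue string.

    K/R -> +1, D/E -> -1, all other residues 0. Raises ``ValueError``
    naming the first offending position for non-amino-acid characters.
    """
    if not residues:
        raise ValueError("empty sequence")
    residues = residues.upper()
    for i, ch in enumerate(residues):
        if ch not in AMINO_ACIDS:
            raise ValueError(
                f"non-amino-acid character {ch!r} at position {i + 1}"
            )
    charges = np.array([RESIDUE_CHARGE.get(ch, 0) for ch in residues], dtype=np.int64)
    return ChargeSequence(residues, charges)


def scd(seq: ChargeSequence) -> float:
    """Sequence charge decoration.

    SCD = (1/L) * sum_{i<j} sigma_i sigma_j sqrt(j - i), with sigma the
    per-residue charge. Blocks of like charge contribute positively,
    alternating opposite charges negatively.
    """
    L = len(seq)
    if L < 2:
        warnings.warn("SCD of a sequence shorter than 2 residues is degenerate; returning 0")
        return 0.0
    q = seq.charges.astype(np.float64)
    # vectorised double sum over ordered pairs i < j
    idx = np.arange(L)
    sep = idx[None, :] - idx[:, None]  # j - i
    mask = sep > 0
    qq = np.outer(q, q)
    total = float(np.sum(qq[mask] * np.sqrt(sep[mask])))
    return total / L


def sequence_metrics(seq: ChargeSequence) -> SequenceMetrics:
    """Charge-composition statistics: counts, fractions, NCPR and SCD."""
    L = len(seq)
    if L < 1:
        raise ValueError("empty sequence")
    n_pos = int(np.sum(seq.charges == 1))
    n_neg = int(np.sum(seq.charges == -1))
    f_plus = n_pos / L
    f_minus = n_neg / L
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        s = scd(seq) if L >= 2 else 0.0
    return SequenceMetrics(
        n_pos=n_pos,
        n_neg=n_neg,
        f_plus=f_plus,
        f_minus=f_minus,
        ncpr=abs(f_plus - f_minus),
        scd=s,
    )


def generate_polyampholyte(
    length: int,
    pattern: str,
    f_plus: float,
    f_minus: float,
    seed: int = 0,
) -> ChargeSequence:
    """Designed charge-pattern sequence over the three-letter {E, K, G} alphabet.

    Letter convention (fixed so fixtures are reproducible): E for -1,
    K for +1, G for neutral.

    patterns:
      ``alternating`` -- E and K interleaved as evenly as possible,
        negative first; leftover charges then neutrals appended.
      ``block`` -- a K block, then an E block, then neutrals.
      ``shuffled`` -- the block composition permuted with the seeded
        generator.
    """
    if length < 1:
        raise ValueError("length must be positive")
    if f_plus < 0 or f_minus < 0 or f_plus + f_minus > 1 + 1e-12:
        raise ValueError("infeasible charge fractions")
    n_pos = f_plus * length
    n_neg = f_minus * length
    if abs(n_pos - round(n_pos)) > 1e-9 or abs(n_neg - round(n_neg)) > 1e-9:
        raise ValueError("length*f_plus and length*f_minus must be integral")
    n_pos, n_neg = int(round(n_pos)), int(round(n_neg))
    n_neu = length - n_pos - n_neg

    if pattern == "alternating":
        out = []
        k_pos, k_neg = n_pos, n_neg
        while k_pos or k_neg:
            if k_neg:
                out.append("E")
                k_neg -= 1
            if k_pos:
                out.append("K")
                k_pos -= 1
        out.extend("G" * n_neu)
        residues = "".join(out)
    elif pattern == "block":
        residues = "K" * n_pos + "E" * n_neg + "G" * n_neu
    elif pattern == "shuffled":
        rng = np.random.default_rng(seed)
        letters = np.array(list("K" * n_pos + "E" * n_neg + "G" * n_neu))
        rng.shuffle(letters)
        residues = "".join(letters)
    else:
        raise ValueError(f"unknown pattern {pattern!r}")
    return assign_charges(residues)


def read_fasta(path: str | Path) -> list[tuple[str, ChargeSequence]]:
    """Parse a FASTA file into ``(identifier, ChargeSequence)`` records.

    Order preserved; wrapped lines concatenated; whitespace and gap
    characters stripped; lowercase accepted. Duplicate identifiers warn.
    """
    path = Path(path)
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            warnings.warn(f"duplicate FASTA identifier {rec.id!r}")
        seen.add(rec.id)
        raw = str(rec.seq).replace("-", "").replace(".", "").strip()
        records.append((rec.id, assign_charges(raw)))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def builtin_sequences() -> dict[str, ChargeSequence]:
    """Designed sequences shipped with the package (currently sv1)."""
    with resources.as_file(
        resources.files("idrslab.data") / "designed_polyampholytes.fasta"
    ) as p:
        return dict(read_fasta(p))


def load_external_sequences(directory: str | Path) -> dict[str, ChargeSequence]:
    """Load user-supplied sequences from every ``*.fasta`` in *directory*.

    Used for sequences the package cannot ship (e.g. the Swc5 IDR
    segments); returns an empty dict when none are present.
    """
    directory = Path(directory)
    out: dict[str, ChargeSequence] = {}
    if not directory.is_dir():
        return out
    for f in sorted(directory.glob("*.fasta")):
        for name, seq in read_fasta(f):
            out[name] = seq
    return out


def iter_metrics(records) -> Iterator[tuple[str, int, SequenceMetrics]]:
    for name, seq in records:
        yield name, len(seq), sequence_metrics(seq)
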