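"""Charge-patterning metrics for K/E polyampholytes.

A "KE" polyampholyte is a chain over the two-letter alphabet {K, E}, where
lysine (K) carries charge +1 and glutamate (E) carries charge -1.  Charge
*patterning* — how the charges are arranged along the chain, from strictly
alternating to fully blocky — controls the strength of homotypic attraction
and is quantified here by the sequence charge decoration (SCD) metric and a
normalized form Ω.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

CHARGE_MAP = {"K": 1.0, "E": -1.0}


@dataclass(frozen=True)
class ChargeSequence:
    """A charged residue sequence with per-residue signed unit charges.

    Parameters
    ----------
    residues : str
        Residue string over the alphabet {K, E}.
    name : str
        Identifier carried through outputs.
    """

    residues: str
    name: str = ""
    charges: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError("sequence must contain at least one residue")
        bad = set(self.residues) - set(CHARGE_MAP)
        if bad:
            raise ValueError(
                f"residues {sorted(bad)} have no charge assignment; "
                f"supported alphabet is {sorted(CHARGE_MAP)}"
            )
        q = np.array([CHARGE_MAP[r] for r in self.residues], dtype=float)
        object.__setattr__(self, "charges", q)
        if abs(q.sum()) > 0.5 and len(q) > 1:
            warnings.warn(
                f"sequence {self.name or self.residues[:10]!r} is not "
                f"charge-neutral (net charge {q.sum():+.0f})",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def net_charge(self) -> int:
        return int(round(self.charges.sum()))


@dataclass(frozen=True)
class PatternMetrics:
    """Summary of a sequence's charge-patterning descriptors."""

    scd: float
    omega: float
    length: int
    net_charge: int


def compute_scd(seq: ChargeSequence) -> float:
    """Sequence charge decoration:  SCD = (1/N) Σ_{i<j} q_i q_j (j-i)^{1/2}.

    SCD is negative for attractive polyampholyte patterning; its magnitude
    grows with charge blockiness.  A single-residue sequence has an empty
    pair sum and returns 0.
    """
    q = seq.charges
    n = len(q)
    if n == 1:
        return 0.0
    # vectorized over pair separations d = j - i: the inner product of the
    # charge track with itself shifted by d counts every pair at that lag.
    total = 0.0
    for d in range(1, n):
        total += np.dot(q[:-d], q[d:]) * np.sqrt(d)
    return float(total / n)


def diblock(length: int, name: str = "") -> ChargeSequence:
    """The maximally blocky neutral sequence K^{n}E^{n} of the given length."""
    if length % 2 != 0:
        raise ValueError("a neutral diblock requires an even length")
    h = length // 2
    return ChargeSequence("K" * h + "E" * h, name=name or f"diblock{length}")


def compute_omega(seq: ChargeSequence) -> float:
    """Normalized SCD:  Ω = SCD(seq) / SCD(diblock of same length, composition).

    The normalizing sequence is the fully blocky arrangement of the same
    residue counts, so Ω ∈ (0, 1] for neutral sequences and Ω = 1 identifies
    the diblock itself.  Undefined for homopolymers (the pair products never
    change sign, the normalization loses meaning).
    """
    counts = {r: seq.residues.count(r) for r in CHARGE_MAP}
    if min(counts.values()) == 0:
        raise ValueError("Ω is undefined for a homopolymer (needs both K and E)")
    blockiest = ChargeSequence("K" * counts["K"] + "E" * counts["E"])
    denom = compute_scd(blockiest)
    return compute_scd(seq) / denom


def delta_omega(p: ChargeSequence, q: ChargeSequence) -> float:
    """Patterning difference ΔΩ = Ω(p) − Ω(q); antisymmetric in its arguments."""
    return compute_omega(p) - compute_omega(q)


def pattern_metrics(seq: ChargeSequence) -> PatternMetrics:
    return PatternMetrics(
        scd=compute_scd(seq),
        omega=compute_omega(seq),
        length=len(seq),
        net_charge=seq.net_charge,
    )


def ncpr_profile(seq: ChargeSequence, window: int) -> np.ndarray:
    """Net charge per residue along the chain: sliding-window mean of charges.

    Windows are centred; at the termini the window is truncated to the
    residues that exist (no padding), so the track always has the sequence's
    length.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 1")
    n = len(seq)
    if window > n:
        raise ValueError(f"window {window} exceeds sequence length {n}")
    half = window // 2
    csum = np.concatenate(([0.0], np.cumsum(seq.charges)))
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


# ---------------------------------------------------------------------------
# sequence input: FASTA / plain text / name->sequence registry


def read_sequences(path: str | Path) -> list[ChargeSequence]:
    """Load charge sequences from FASTA or one-sequence-per-line text.

    A line of the form ``NAME<TAB or spaces>SEQUENCE`` is treated as a
    registry entry (name → string); bare lines are named seq1, seq2, ...
    """
    path = Path(path)
    text = path.read_text()
    seqs: list[ChargeSequence] = []
    if text.lstrip().startswith(">"):
        from Bio import SeqIO

        for rec in SeqIO.parse(str(path), "fasta"):
            seqs.append(ChargeSequence(str(rec.seq).upper(), name=rec.id))
        return seqs
    for i, line in enumerate(text.splitlines()):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) >= 2:
            seqs.append(ChargeSequence(parts[-1].upper(), name=parts[0]))
        else:
            seqs.append(ChargeSequence(parts[0].upper(), name=f"seq{i + 1}"))
    if not seqs:
        raise ValueError(f"no sequences found in {path}")
    return seqs


def write_fasta(seqs: list[ChargeSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.name or 'seq'}\n{s.residues}\n")
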