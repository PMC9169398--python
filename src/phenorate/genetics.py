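"""QTL allele operators for the Jamapa x Calima recombinant-inbred family.

Each line is identified by its parental origin at 12 flowering-time QTL
(TF1..TF12), coded as a signed unit "allele operator": +1 for the Calima
allele, -1 for the Jamapa allele.  The +-1 algebra makes main effects and
products (QTL x QTL, environment x QTL) directly usable as regressors.
A 0 operator is the hypothetical mid-parent value; it never occurs in an
inbred line and must be requested explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np

N_LOCI = 12
LOCUS_NAMES: tuple[str, ...] = tuple(f"TF{i}" for i in range(1, N_LOCI + 1))

_ALLELE_CODE = {"Calima": 1, "Jamapa": -1}


@dataclass(frozen=True)
class Locus:
    """A flowering-time QTL: name, chromosome and linkage-map position (cM)."""

    name: str
    chromosome: str
    position_cm: float

    def __post_init__(self) -> None:
        if self.position_cm < 0:
            raise ValueError(f"map position must be non-negative: {self.name}")


#: The 12 TTF QTL with their chromosomes and map positions (cM).
#: Metadata only: positions feed optional linkage-aware simulation, never the
#: rate model itself.
LOCUS_CATALOG: tuple[Locus, ...] = (
    Locus("TF1", "Chrom1", 22.1),
    Locus("TF2", "Chrom1", 42.1),
    Locus("TF3", "Chrom1", 58.8),
    Locus("TF4", "Chrom1", 70.0),
    Locus("TF5", "Chrom3", 38.2),
    Locus("TF6", "Chrom3", 49.2),
    Locus("TF7", "Chrom4", 42.2),
    Locus("TF8", "Chrom6", 31.3),
    Locus("TF9", "Chrom7", 11.7),
    Locus("TF10", "Chrom7", 98.7),
    Locus("TF11", "Chrom11", 2.1),
    Locus("TF12", "Chrom11", 9.3),
)


@dataclass(frozen=True)
class QTLGenotype:
    """An inbred line's allele operators at the 12 TTF loci.

    Parameters
    ----------
    id
        Text label ("Calima", "RIJC031", ...).
    operators
        Ordered 12-vector over {+1, -1} in TF1..TF12 order.  0 entries are
        the mid-parent hypothetical and must be enabled with
        ``allow_midparent=True``.
    """

    id: str
    operators: tuple[int, ...]
    allow_midparent: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        ops = tuple(int(o) for o in self.operators)
        if len(ops) != N_LOCI:
            raise ValueError(
                f"genotype {self.id!r} has {len(ops)} operators, expected {N_LOCI}"
            )
        allowed = {-1, 0, 1} if self.allow_midparent else {-1, 1}
        bad = [LOCUS_NAMES[i] for i, o in enumerate(ops) if o not in allowed]
        if bad:
            raise ValueError(
                f"genotype {self.id!r}: operators at {', '.join(bad)} not in "
                f"{sorted(allowed)} (0 is mid-parent and needs allow_midparent=True)"
            )
        object.__setattr__(self, "operators", ops)

    def operator(self, locus: str) -> int:
        return self.operators[_locus_index(locus)]

    def as_array(self) -> np.ndarray:
        return np.asarray(self.operators, dtype=float)

    def allele_calls(self) -> dict[str, str]:
        """Recover parental-origin labels; inverse of :func:`encode_genotype`."""
        rev = {1: "Calima", -1: "Jamapa", 0: "mid-parent"}
        return {name: rev[o] for name, o in zip(LOCUS_NAMES, self.operators)}


def _locus_index(locus: str) -> int:
    try:
        return LOCUS_NAMES.index(locus)
    except ValueError:
        raise KeyError(f"unknown locus {locus!r}; expected one of TF1..TF12") from None


CALIMA = QTLGenotype("Calima", (1,) * N_LOCI)
JAMAPA = QTLGenotype("Jamapa", (-1,) * N_LOCI)
MIDPARENT = QTLGenotype("mid-parent", (0,) * N_LOCI, allow_midparent=True)


def encode_genotype(
    allele_calls: Mapping[str, str] | Sequence[str], id: str = ""
) -> QTLGenotype:
    """Build a genotype from per-locus parental-origin labels.

    ``allele_calls`` is either a mapping locus name -> {"Calima", "Jamapa"}
    covering all 12 loci, or a 12-sequence of labels in TF1..TF12 order.
    Calima maps to +1 and Jamapa to -1.
    """
    if isinstance(allele_calls, Mapping):
        missing = [n for n in LOCUS_NAMES if n not in allele_calls]
        if missing:
            raise ValueError(f"missing allele calls at {', '.join(missing)}")
        extra = [n for n in allele_calls if n not in LOCUS_NAMES]
        if extra:
            raise KeyError(f"unknown locus {extra[0]!r}; expected one of TF1..TF12")
        labels = [allele_calls[n] for n in LOCUS_NAMES]
    else:
        labels = list(allele_calls)
        if len(labels) != N_LOCI:
            raise ValueError(f"expected {N_LOCI} allele calls, got {len(labels)}")
    ops = []
    for name, lab in zip(LOCUS_NAMES, labels):
        if lab not in _ALLELE_CODE:
            raise ValueError(
                f"unknown allele label {lab!r} at {name}; expected 'Calima' or 'Jamapa'"
            )
        ops.append(_ALLELE_CODE[lab])
    return QTLGenotype(id or "genotype", tuple(ops))


def substitute_alleles(
    base: QTLGenotype,
    loci: Iterable[str],
    donor: QTLGenotype,
    id: str | None = None,
) -> QTLGenotype:
    """Replace ``base``'s alleles at ``loci`` with the donor's operators.

    Used to build synthetic near-isogenic genotypes, e.g. replacing in
    Jamapa its TF1, TF2 and TF3 alleles with those of Calima gives the
    "J-CTF1,2,3" line.  ``base`` is not modified.
    """
    loci = list(loci)
    idx = [_locus_index(l) for l in loci]
    ops = list(base.operators)
    for i in idx:
        ops[i] = donor.operators[i]
    if id is None:
        id = f"{base.id}+{donor.id}@{','.join(loci)}" if loci else base.id
    allow = any(o == 0 for o in ops)
    return QTLGenotype(id, tuple(ops), allow_midparent=allow)


def enumerate_family(n_loci: int = N_LOCI) -> list[QTLGenotype]:
    """All 2**n_loci homozygous allele combinations, lexicographically ordered.

    Ordering is deterministic: -1 sorts before +1 and TF1 is the most
    significant locus, so ``family[0]`` is all-Jamapa and ``family[-1]`` is
    all-Calima.  For the full 12-locus catalog this is the 4096-member
    synthetic family.
    """
    if not 1 <= n_loci <= 20 or n_loci > N_LOCI:
        raise ValueError(f"n_loci must be in [1, {N_LOCI}], got {n_loci}")
    family = []
    # loci beyond n_loci stay fixed at the Jamapa allele so every genotype is
    # a valid 12-locus inbred; only the leading n_loci vary
    for k, combo in enumerate(product((-1, 1), repeat=n_loci)):
        ops = combo + (-1,) * (N_LOCI - n_loci)
        family.append(QTLGenotype(f"SYN{k:04d}", ops))
    return family
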