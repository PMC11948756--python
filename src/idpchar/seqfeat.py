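"""Sequence-level disorder descriptors and labeling stoichiometry.

The charge-hydropathy classification places a protein in the plane of mean
Kyte-Doolittle hydropathy (rescaled to [0, 1]) versus absolute mean net
charge; the canonical linear discriminant separating natively folded from
natively unfolded proteins is

    <H>_boundary = (<q> + 1.151) / 2.785,

with the disordered side above/left of the line (low hydropathy, high net
charge).  Chain statistics (average mass, mean residue weight) support
molar-mass bookkeeping for CD normalization and AUC species tables; the
degree of labeling converts a dye/protein absorbance pair to dyes per
molecule.
"""

from __future__ import annotations

import importlib.resources
import urllib.request
from dataclasses import dataclass
from pathlib import Path

from .constants import AMINO_ACID_MASS_DA, KYTE_DOOLITTLE, WATER_MASS_DA
from .exceptions import ValidationError

__all__ = [
    "SequenceRecord", "ChargeHydropathyPoint", "ChainStats", "LabelingMeasurement",
    "charge_hydropathy", "chain_stats", "degree_of_labeling",
    "load_reference_sequence", "fetch_reference_sequence", "REFERENCE_ACCESSION",
]

#: Accession of the study protein (human TCF4 isoform I-).
REFERENCE_ACCESSION = "P15884-16"

_ALLOWED = set(AMINO_ACID_MASS_DA) | {"X"}


@dataclass
class SequenceRecord:
    """An amino-acid chain; standard residues plus X, stored uppercase."""

    residues: str
    accession: str | None = None

    def __post_init__(self):
        self.residues = self.residues.upper().replace("*", "").replace("-", "")
        if not self.residues:
            raise ValidationError("empty sequence")
        bad = sorted(set(self.residues) - _ALLOWED)
        if bad:
            raise ValidationError(f"non-amino-acid symbols in sequence: {bad}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class ChargeHydropathyPoint:
    mean_hydropathy: float
    mean_net_charge: float
    classification: str  # ordered-side | disordered-side
    boundary_hydropathy: float


@dataclass
class ChainStats:
    length: int
    mass_da: float
    mrw_da: float

    @property
    def dimer_mass_kda(self) -> float:
        return 2 * self.mass_da / 1e3


@dataclass
class LabelingMeasurement:
    """Absorbance pair and extinction coefficients for dye stoichiometry."""

    a_max: float
    a_280: float
    eps_protein: float  # M^-1 cm^-1 at 280 nm
    eps_max: float  # M^-1 cm^-1 at the dye maximum
    cf: float  # dye 280-nm correction factor

    def __post_init__(self):
        if self.a_max < 0 or self.a_280 < 0:
            raise ValidationError("absorbances must be non-negative")
        if self.eps_protein <= 0 or self.eps_max <= 0:
            raise ValidationError("extinction coefficients must be positive")


def charge_hydropathy(seq: SequenceRecord) -> ChargeHydropathyPoint:
    """Charge-hydropathy coordinates and ordered/disordered classification.

    Hydropathy per residue is (KD + 4.5)/9; the net charge counts K/R as
    +1 and D/E as -1 at neutral pH (H neutral, termini ignored).  X
    residues are excluded from the hydropathy average but count toward
    length for the charge density.
    """
    if len(seq) < 20:
        raise ValidationError("charge-hydropathy needs at least 20 residues")
    scored = [r for r in seq.residues if r != "X"]
    if not scored:
        raise ValidationError("sequence contains only X residues")
    h = sum((KYTE_DOOLITTLE[r] + 4.5) / 9.0 for r in scored) / len(scored)
    pos = sum(seq.residues.count(r) for r in "KR")
    neg = sum(seq.residues.count(r) for r in "DE")
    q = abs(pos - neg) / len(seq)
    boundary = (q + 1.151) / 2.785
    cls = "disordered-side" if h < boundary else "ordered-side"
    return ChargeHydropathyPoint(mean_hydropathy=h, mean_net_charge=q,
                                 classification=cls, boundary_hydropathy=boundary)


def chain_stats(seq: SequenceRecord, x_mass_da: float | None = None) -> ChainStats:
    """Length, isotope-averaged chain mass and mean residue weight (mass/N)."""
    masses = dict(AMINO_ACID_MASS_DA)
    if "X" in seq.residues:
        if x_mass_da is None:
            raise ValidationError("sequence contains X; supply x_mass_da to compute mass")
        masses["X"] = x_mass_da
    n = len(seq)
    mass = sum(masses[r] for r in seq.residues) - (n - 1) * WATER_MASS_DA
    return ChainStats(length=n, mass_da=mass, mrw_da=mass / n)


def degree_of_labeling(m: LabelingMeasurement) -> float:
    """Average dyes per protein: A_max ε_prot / ((A_280 - A_max CF) ε_max)."""
    denom = (m.a_280 - m.a_max * m.cf) * m.eps_max
    if denom <= 0:
        raise ValidationError("degenerate measurement: protein absorbance "
                              "does not exceed the dye 280-nm contribution")
    return m.a_max * m.eps_protein / denom


def _packaged_reference_path() -> Path:
    return Path(str(importlib.resources.files("idpchar") / "data" /
                    f"{REFERENCE_ACCESSION}.fasta"))


def load_reference_sequence(path: str | Path | None = None) -> SequenceRecord:
    """Load the study protein (UniProt P15884-16) from a FASTA file.

    Looks in the packaged data directory unless ``path`` is given.  The
    sequence is not redistributed with the package; fetch it once with
    :func:`fetch_reference_sequence` on a networked machine.
    """
    from .io import read_fasta  # local import to avoid a cycle
    p = Path(path) if path is not None else _packaged_reference_path()
    if not p.exists():
        raise FileNotFoundError(
            f"reference sequence FASTA not found at {p}; run "
            "idpchar.seqfeat.fetch_reference_sequence() with network access")
    return read_fasta(p)[0]


def fetch_reference_sequence(dest: str | Path | None = None) -> Path:
    """Download the P15884-16 isoform FASTA from UniProt (needs network)."""
    dest = Path(dest) if dest is not None else _packaged_reference_path()
    url = f"https://rest.uniprot.org/uniprotkb/{REFERENCE_ACCESSION}.fasta"
    with urllib.request.urlopen(url, timeout=30) as resp:
        data = resp.read()
    dest.parent.mkdir(parents=True, exist_ok=True)
    dest.write_bytes(data)
    return dest
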