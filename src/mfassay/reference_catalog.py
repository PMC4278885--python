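"""Catalog of DNA reference duplexes and their characteristic forces.

A reference duplex is described by its length, pulling geometry and
stabilizing modifications, and maps to a characteristic (most probable)
rupture force and from there to an effective Bell bond for the kinetic
model.  Two geometry anchors are fixed: ~15 pN for a duplex opened in
zipper mode (length-independent) and ~65 pN for a 40 bp duplex pulled in
shear mode, the overstretching plateau that short oligos cannot exceed.
Intermediate shear forces follow a linear-in-length default model capped
at the plateau.

Stabilization increments (propynyl bases, minor-groove polyamide ligands)
are NOT physical measurements: the field only reports that they strengthen
the duplex, with ligand effect ordered by affinity.  The defaults here are
invented, tunable magnitudes chosen so that simulated readouts reproduce
the qualitative ordering unmodified < propynyl < +P3 < +P1 < +P2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from mfassay.bond_kinetics import BellBond, ForceRamp, bond_from_characteristic_force

__all__ = [
    "ZIPPER_FORCE",
    "SHEAR_PLATEAU_FORCE",
    "SHEAR_PLATEAU_BP",
    "PROPYNYL_FORCE_PER_BASE",
    "DNAReference",
    "StabilizerLigand",
    "DEFAULT_LIGANDS",
    "characteristic_force",
    "effective_reference_bond",
]

#: Characteristic force of a duplex opened base-by-base (zipper mode), pN.
ZIPPER_FORCE = 15.0
#: Shear-mode plateau force (overstretching transition), pN.
SHEAR_PLATEAU_FORCE = 65.0
#: Duplex length at which shear mode reaches the plateau, bp.
SHEAR_PLATEAU_BP = 40
#: Invented default: force added per propynyl-substituted pyrimidine, pN.
PROPYNYL_FORCE_PER_BASE = 0.3


@dataclass(frozen=True)
class StabilizerLigand:
    """A minor-groove ligand that stabilizes the duplex when saturated.

    ``delta_force`` is the characteristic-force increment it confers; the
    occupancy model is binary -- the increment applies only when the ligand
    is present at >= 1000x its dissociation constant.
    """

    name: str
    kd_pM: float
    concentration_uM: float
    delta_force: float

    def __post_init__(self) -> None:
        if self.kd_pM <= 0:
            raise ValueError(f"kd_pM must be > 0, got {self.kd_pM}")
        if self.concentration_uM <= 0:
            raise ValueError(
                f"concentration_uM must be > 0, got {self.concentration_uM}"
            )
        if self.delta_force < 0:
            raise ValueError(f"delta_force must be >= 0, got {self.delta_force}")

    @property
    def saturated(self) -> bool:
        """True when concentration >= 1000 x Kd (1 uM = 1e6 pM)."""
        return self.concentration_uM * 1.0e6 >= 1000.0 * self.kd_pM


# Invented delta_force defaults (see module docstring); ordering follows
# affinity: P2 (44 pM) > P1 (105 pM) > P3 (1442 pM).  Magnitudes are sized
# so a 20 bp + ligand reference outranks a propynyl-stabilized 40 bp one.
DEFAULT_LIGANDS: dict[str, StabilizerLigand] = {
    "P1": StabilizerLigand("P1", kd_pM=105.0, concentration_uM=1.0, delta_force=47.0),
    "P2": StabilizerLigand("P2", kd_pM=44.0, concentration_uM=1.0, delta_force=55.0),
    # P3's weaker affinity needs > 1.44 uM to clear the binary 1000x-Kd
    # saturation rule, hence the higher default concentration.
    "P3": StabilizerLigand("P3", kd_pM=1442.0, concentration_uM=2.0, delta_force=42.0),
}


@dataclass(frozen=True)
class DNAReference:
    """A reference duplex: length, pulling geometry, stabilization.

    ``sequence``/``complement`` are optional plain strands (e.g. read from
    FASTA); when both are given they are validated for length and
    Watson-Crick complementarity only.
    """

    name: str
    length_bp: int
    geometry: Literal["shear", "zipper"]
    propynyl_count: int = 0
    ligand: StabilizerLigand | None = None
    sequence: str | None = None
    complement: str | None = None

    def __post_init__(self) -> None:
        if self.geometry not in ("shear", "zipper"):
            raise ValueError(f"geometry must be 'shear' or 'zipper', got {self.geometry!r}")
        if not 1 <= self.length_bp <= 100:
            raise ValueError(f"length_bp must be in [1, 100], got {self.length_bp}")
        if not 0 <= self.propynyl_count <= self.length_bp:
            raise ValueError(
                f"propynyl_count must be in [0, length_bp], got {self.propynyl_count}"
            )
        if self.sequence is not None:
            self._validate_sequence()

    def _validate_sequence(self) -> None:
        seq = self.sequence.upper()
        if len(seq) != self.length_bp:
            raise ValueError(
                f"sequence length {len(seq)} != length_bp {self.length_bp}"
            )
        if set(seq) - set("ACGT"):
            raise ValueError(f"sequence contains non-ACGT characters: {seq}")
        if self.complement is not None:
            comp = self.complement.upper()
            if len(comp) != self.length_bp:
                raise ValueError(
                    f"complement length {len(comp)} != length_bp {self.length_bp}"
                )
            pairs = {"A": "T", "T": "A", "C": "G", "G": "C"}
            expected = "".join(pairs[b] for b in reversed(seq))
            if comp != expected:
                raise ValueError("complement strand is not the reverse complement")


def characteristic_force(reference: DNAReference) -> float:
    """Characteristic rupture force of a reference duplex, pN.

    zipper: the 15 pN anchor regardless of length.  shear: linear in length
    up to the 40 bp / 65 pN plateau.  Propynyl substitutions and a saturated
    ligand add their (default, invented) increments.
    """
    if reference.geometry == "zipper":
        base = ZIPPER_FORCE
    else:
        frac = min(reference.length_bp, SHEAR_PLATEAU_BP) / SHEAR_PLATEAU_BP
        base = SHEAR_PLATEAU_FORCE * frac
    force = base + reference.propynyl_count * PROPYNYL_FORCE_PER_BASE
    if reference.ligand is not None and reference.ligand.saturated:
        force += reference.ligand.delta_force
    return force


def effective_reference_bond(
    reference: DNAReference, ramp: ForceRamp, dx: float = 1.0
) -> BellBond:
    """Bell bond whose most probable rupture force matches the catalog force."""
    return bond_from_characteristic_force(
        characteristic_force(reference), ramp, dx=dx, label=reference.name
    )
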