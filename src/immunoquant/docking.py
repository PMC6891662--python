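"""Post-processing of molecular-docking pose tables.

A docking run produces several candidate conformers per ligand, each with an
estimated binding free energy ΔG (kcal/mol, negative = favourable).  This
module selects the best (lowest-energy) pose per ligand, converts ΔG to an
inhibition constant through the Boltzmann relation

    K_i = exp(ΔG / (R·T)),   R = 1.98720e-3 kcal·mol⁻¹·K⁻¹,

and ranks ligands by affinity.  Running the docking engine itself is out of
scope; the input is a plain table ``ligand, conformer, binding_energy_kcal_mol``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .errors import DomainError

#: Gas constant in kcal·mol⁻¹·K⁻¹ (the value AutoDock-style engines use).
GAS_CONSTANT_KCAL = 1.98720e-3

#: Standard temperature for the ΔG ↔ K_i conversion, kelvin.
DEFAULT_TEMPERATURE = 298.15

#: Best-pose binding energies (kcal/mol) of a panel of long-chain fatty
#: acids and phenolic acids docked against a venom acyl-CoA-synthetase-like
#: protein; used as the worked example and reference dataset.
FATTY_ACID_PANEL = {
    "Arachidonic acid": -8.06,
    "Caffeic acid": -6.40,
    "Ferulic acid": -6.47,
    "Linoleic acid": -6.37,
    "Linolenic acid": -8.35,
    "Palmitic acid": -8.69,
    "p-Coumarate": -6.41,
}


@dataclass(frozen=True)
class DockingPose:
    """One docked conformer of one ligand."""

    ligand: str
    conformer_id: int
    binding_energy: float  # kcal/mol

    def __post_init__(self) -> None:
        if not math.isfinite(self.binding_energy):
            raise DomainError(f"non-finite binding energy for {self.ligand!r}")


@dataclass(frozen=True)
class LigandAffinity:
    """Best pose of a ligand with its derived inhibition constant."""

    ligand: str
    best_energy: float  # kcal/mol
    ki: float  # molar
    rank: int  # 1-based, ascending binding energy
    temperature: float = DEFAULT_TEMPERATURE
    gas_constant: float = field(default=GAS_CONSTANT_KCAL, repr=False)

    @property
    def ki_uM(self) -> float:
        """Inhibition constant in micromolar, the unit affinity tables print."""
        return self.ki * 1e6


def ki_from_energy(dg: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Convert a binding free energy to an inhibition constant (molar).

    Parameters
    ----------
    dg : float
        Binding free energy in kcal/mol.  More negative = tighter binding.
    temperature : float
        Absolute temperature in kelvin (default 298.15 K).

    Returns
    -------
    float
        K_i = exp(ΔG/RT) in molar units; strictly increasing in ``dg``.
    """
    if not math.isfinite(dg):
        raise DomainError("binding energy must be finite")
    if temperature <= 0:
        raise DomainError("temperature must be positive (kelvin)")
    return math.exp(dg / (GAS_CONSTANT_KCAL * temperature))


def energy_from_ki(ki: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Inverse of :func:`ki_from_energy`: ΔG = R·T·ln(K_i) in kcal/mol."""
    if not (ki > 0):
        raise DomainError("inhibition constant must be positive")
    if temperature <= 0:
        raise DomainError("temperature must be positive (kelvin)")
    return GAS_CONSTANT_KCAL * temperature * math.log(ki)


def select_best_pose(poses: "list[DockingPose] | pd.DataFrame") -> DockingPose:
    """Return the pose with the lowest binding energy.

    Ties are broken by the lowest conformer id so the choice is deterministic.
    """
    if isinstance(poses, pd.DataFrame):
        poses = [
            DockingPose(str(r.ligand), int(r.conformer), float(r.binding_energy_kcal_mol))
            for r in poses.itertuples()
        ]
    if not poses:
        raise DomainError("no poses supplied")
    return min(poses, key=lambda p: (p.binding_energy, p.conformer_id))


def rank_ligands(
    poses: pd.DataFrame, temperature: float = DEFAULT_TEMPERATURE
) -> list[LigandAffinity]:
    """Best pose per ligand → K_i → rank ascending by binding energy.

    Parameters
    ----------
    poses : pandas.DataFrame
        Columns ``ligand``, ``conformer``, ``binding_energy_kcal_mol``; one row
        per docked conformer.  Multiple blocks with the same ligand name are
        merged (a warning is emitted, since that usually signals a
        concatenation mistake upstream).
    temperature : float
        Kelvin, used for the ΔG → K_i conversion.

    Returns
    -------
    list of LigandAffinity
        Sorted by rank; ranking by ΔG coincides with ranking by K_i because
        the conversion is strictly monotone.
    """
    required = {"ligand", "conformer", "binding_energy_kcal_mol"}
    missing = required - set(poses.columns)
    if missing:
        raise DomainError(f"pose table missing columns: {sorted(missing)}")
    if len(poses) == 0:
        raise DomainError("empty pose table")

    # Non-contiguous repeats of a ligand name are merged into one ligand.
    runs = (poses["ligand"] != poses["ligand"].shift()).cumsum()
    if runs.groupby(poses["ligand"]).nunique().gt(1).any():
        warnings.warn("duplicate ligand names merged", stacklevel=2)

    best = []
    for ligand, grp in poses.groupby("ligand", sort=False):
        pose = select_best_pose(grp)
        best.append((ligand, pose.binding_energy))
    best.sort(key=lambda t: (t[1], t[0]))
    return [
        LigandAffinity(
            ligand=ligand,
            best_energy=dg,
            ki=ki_from_energy(dg, temperature),
            rank=i + 1,
            temperature=temperature,
        )
        for i, (ligand, dg) in enumerate(best)
    ]


def affinity_table(affinities: list[LigandAffinity]) -> pd.DataFrame:
    """Flatten ranked affinities into the report layout ligand/ΔG/K_i(μM)/rank."""
    return pd.DataFrame(
        {
            "ligand": [a.ligand for a in affinities],
            "best_energy": [a.best_energy for a in affinities],
            "ki_uM": [a.ki_uM for a in affinities],
            "rank": [a.rank for a in affinities],
        }
    )
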