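"""Model parameters, ligand specifications, and unit conversions.

Internal units are molar and seconds throughout; ligand doses (ng/mL, the
unit used at the bench) and receptor copy numbers are converted at the
boundary.

Rate-constant roles
-------------------
``k1``  ligand-receptor association (M^-1 s^-1)
``k2``  reporter (tandem SH2) association to an active dimer tail (M^-1 s^-1)
``k3``  dissociation of ligand-bound (active) dimers (s^-1); scaled by gamma,
        the ligand's fold-change in the dimerization affinity of ligand-bound
        receptors
``k4``  reporter dissociation (s^-1)
``k5``  receptor dimerization (M^-1 s^-1), shared by ligand-free and
        ligand-bound receptors (dimerization + autophosphorylation lumped)
``k6``  dissociation of ligand-free, inactive dimers (s^-1)
``k7``  ligand dissociation (s^-1); scaled by beta, the ligand's fold-change
        in receptor binding affinity

Note: one could also read "k5 and k7 represent forward and reverse rates for
the lumped dimerization process" literally, which would make k7 the active
dimer off-rate; that reading is incompatible with beta (a *binding* affinity
scale) acting on k7 and gamma (a *dimerization* affinity scale) acting on k3,
so the beta/gamma assignment above is used.

Default values: ligand binding (k1, k7) and reporter binding (k2, k4) sit in
the literature range for EGF-EGFR (Kd ~ 2 nM) and ZAP70-tSH2/ITAM (Kd ~ 10
nM) kinetics; k6 = 5e-3 s^-1; the lumped dimerization constants (k5, k3)
were calibrated so that simulated high-dose EGF responses show the observed
fast initial phase (tens of seconds) followed by a slow further rise over
~30 min, and gamma = 100 converts the response to a peak-then-plateau.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "AVOGADRO",
    "ModelParameters",
    "LigandSpec",
    "EGF",
    "molecules_to_concentration",
    "dose_to_concentration",
    "apply_ligand_scaling",
    "load_config",
    "save_config",
]

AVOGADRO = 6.02214076e23  # 1/mol

#: default molecular weight (g/mol) used for all ligands; human EGF is
#: ~6.22 kDa and the low-affinity ligands are of comparable size.  Doses are
#: compared in ng/mL, so this only sets an overall concentration scale.
DEFAULT_LIGAND_MW = 6222.0


def molecules_to_concentration(count: float, radius_um: float) -> float:
    """Convert a copy number per cell to molar, treating the cell as a sphere.

    ``radius_um`` is the cell radius in micrometres.
    """
    if radius_um <= 0:
        raise ValueError("cell radius must be positive")
    if count < 0:
        raise ValueError("molecule count must be nonnegative")
    volume_l = (4.0 / 3.0) * np.pi * (radius_um * 1e-6) ** 3 * 1e3  # m^3 -> L
    return count / (AVOGADRO * volume_l)


def dose_to_concentration(dose_ng_ml: float, molecular_weight: float) -> float:
    """Convert a dose in ng/mL to molar given the ligand molecular weight."""
    if molecular_weight <= 0:
        raise ValueError("molecular weight must be positive")
    if dose_ng_ml < 0:
        raise ValueError("dose must be nonnegative")
    return dose_ng_ml * 1e-6 / molecular_weight  # ng/mL == 1e-6 g/L


@dataclass(frozen=True)
class ModelParameters:
    """Rate constants and totals of the receptor/reporter system.

    ``receptor_total`` and ``reporter_total`` are molar; by default both are
    derived from 250,000 receptors in a 10 um sphere and a 1:1
    receptor:reporter molar ratio.
    """

    k1: float = 1.0e7     # M^-1 s^-1  ligand on
    k2: float = 1.0e7     # M^-1 s^-1  reporter on
    k3: float = 1.0e-4    # s^-1       active-dimer off (gamma-scaled)
    k4: float = 1.0e-1    # s^-1       reporter off
    k5: float = 1.0e4     # M^-1 s^-1  dimerization on
    k6: float = 5.0e-3    # s^-1       inactive-dimer off
    k7: float = 2.0e-2    # s^-1       ligand off (beta-scaled)
    receptors_per_cell: float = 250_000.0
    cell_radius_um: float = 10.0
    receptor_total: float | None = None
    reporter_total: float | None = None

    def __post_init__(self):
        if self.receptor_total is None:
            object.__setattr__(
                self, "receptor_total",
                molecules_to_concentration(self.receptors_per_cell,
                                           self.cell_radius_um))
        if self.reporter_total is None:
            # receptor and reporter at a 1:1 molar ratio by default
            object.__setattr__(self, "reporter_total", self.receptor_total)
        for name in ("k1", "k2", "k3", "k4", "k5", "k6", "k7",
                     "receptor_total", "reporter_total"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be nonnegative and finite")

    @property
    def rate_vector(self) -> np.ndarray:
        """k1..k7 as a float vector (kernel input)."""
        return np.array([self.k1, self.k2, self.k3, self.k4,
                         self.k5, self.k6, self.k7], dtype=float)

    def replace(self, **kw) -> "ModelParameters":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class LigandSpec:
    """A ligand's identity: affinity scalings, molecular weight, and dose.

    ``beta`` multiplies the ligand off-rate k7 (fold-reduction in binding
    affinity vs EGF); ``gamma`` multiplies the active-dimer off-rate k3
    (fold-reduction in dimerization affinity of ligand-bound receptors).
    ``beta = gamma = 1`` is the EGF base case.
    """

    name: str = "EGF"
    beta: float = 1.0
    gamma: float = 1.0
    molecular_weight: float = DEFAULT_LIGAND_MW
    dose_ng_ml: float = 0.0

    def __post_init__(self):
        if self.beta <= 0 or self.gamma <= 0:
            raise ValueError("beta and gamma must be positive")
        if self.molecular_weight <= 0:
            raise ValueError("molecular weight must be positive")
        if self.dose_ng_ml < 0:
            raise ValueError("dose must be nonnegative")

    @property
    def concentration(self) -> float:
        """Clamped free-ligand concentration (molar) implied by the dose."""
        return dose_to_concentration(self.dose_ng_ml, self.molecular_weight)

    def at_dose(self, dose_ng_ml: float) -> "LigandSpec":
        return dataclasses.replace(self, dose_ng_ml=dose_ng_ml)

    def scaled(self, beta: float, gamma: float) -> "LigandSpec":
        """Compose additional fold-changes onto this ligand."""
        return dataclasses.replace(self, beta=self.beta * beta,
                                   gamma=self.gamma * gamma)


EGF = LigandSpec(name="EGF", beta=1.0, gamma=1.0)


def apply_ligand_scaling(params: ModelParameters, ligand: LigandSpec
                         ) -> ModelParameters:
    """Return a copy of ``params`` with k7 <- beta*k7 and k3 <- gamma*k3."""
    if ligand.beta <= 0 or ligand.gamma <= 0:
        raise ValueError("beta and gamma must be positive")
    return params.replace(k3=ligand.gamma * params.k3,
                          k7=ligand.beta * params.k7)


# ---------------------------------------------------------------------------
# configuration files

_PARAM_FIELDS = ("k1", "k2", "k3", "k4", "k5", "k6", "k7",
                 "receptors_per_cell", "cell_radius_um",
                 "receptor_total", "reporter_total")
_LIGAND_FIELDS = ("name", "beta", "gamma", "molecular_weight", "dose_ng_ml")


def load_config(path: str | Path) -> tuple[ModelParameters, LigandSpec]:
    """Read a YAML/JSON config with ``parameters`` and ``ligand`` sections."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data)}")
    pdata = data.get("parameters", {})
    ldata = data.get("ligand", {})
    unknown = set(pdata) - set(_PARAM_FIELDS)
    if unknown:
        raise ValueError(f"unknown parameter fields: {sorted(unknown)}")
    unknown = set(ldata) - set(_LIGAND_FIELDS)
    if unknown:
        raise ValueError(f"unknown ligand fields: {sorted(unknown)}")
    return ModelParameters(**pdata), LigandSpec(**ldata)


def save_config(path: str | Path, params: ModelParameters,
                ligand: LigandSpec) -> None:
    path = Path(path)
    data = {
        "units": {"rates": "per-second or per-molar-second",
                  "totals": "molar", "dose": "ng/mL",
                  "molecular_weight": "g/mol"},
        "parameters": {f: getattr(params, f) for f in _PARAM_FIELDS},
        "ligand": {f: getattr(ligand, f) for f in _LIGAND_FIELDS},
    }
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
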