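"""Radial atomic environment vectors (AEVs).

For a ligand heavy atom i, the radial AEV collects Gaussian-smeared,
cosine-cutoff-weighted densities of surrounding protein atoms, separated by
ECIF protein atom type t and Gaussian shift/width (R_s, eta):

    g_i[t, m] = sum_{j : type(j)=t} exp(-eta (R_ij - R_s)^2) * f_c(R_ij)

with the continuous cutoff

    f_c(R) = 1/2 (cos(pi R / R_c) + 1)   for R <= R_c, else 0.

The defaults (R_c = 5.1 A, sixteen R_s shifts from 0.80 to 4.83 A, a single
eta = 19.7 1/A^2) follow the ANI-2x radial parameter set, giving vectors of
length N*L*K = 22 * 16 * 1 = 352.  Entries are indexed lexicographically by
(type, R_s, eta), with the 22 types in the packaged table order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .complex_io import AtomRecord, ProteinStructure
from .ecif_types import N_PROTEIN_TYPES

DEFAULT_RC = 5.1
DEFAULT_RS = (
    0.80, 1.07, 1.34, 1.61, 1.88, 2.14, 2.41, 2.68,
    2.95, 3.22, 3.49, 3.76, 4.03, 4.29, 4.56, 4.83,
)
DEFAULT_ETA = (19.7,)


@dataclass(frozen=True)
class AEVParams:
    """Radial AEV hyperparameters (all lengths in Angstrom, eta in 1/A^2)."""

    Rc: float = DEFAULT_RC
    Rs_values: tuple[float, ...] = DEFAULT_RS
    eta_values: tuple[float, ...] = DEFAULT_ETA
    n_types: int = N_PROTEIN_TYPES

    def __post_init__(self):
        if self.Rc <= 0:
            raise ValueError("Rc must be positive")
        if not self.Rs_values or not self.eta_values:
            raise ValueError("need at least one Rs and one eta")
        if any(rs >= self.Rc for rs in self.Rs_values):
            raise ValueError("all Rs shifts must lie inside the cutoff")

    @property
    def L(self) -> int:
        return len(self.Rs_values)

    @property
    def K(self) -> int:
        return len(self.eta_values)

    @property
    def n_shells(self) -> int:
        """Number of (R_s, eta) combinations per type."""
        return self.L * self.K

    @property
    def length(self) -> int:
        """Total AEV length N*L*K."""
        return self.n_types * self.L * self.K

    def to_dict(self) -> dict:
        return {
            "Rc": self.Rc,
            "Rs_values": list(self.Rs_values),
            "eta_values": list(self.eta_values),
            "n_types": self.n_types,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AEVParams":
        return cls(
            Rc=float(d["Rc"]),
            Rs_values=tuple(float(v) for v in d["Rs_values"]),
            eta_values=tuple(float(v) for v in d["eta_values"]),
            n_types=int(d.get("n_types", N_PROTEIN_TYPES)),
        )


def cutoff(Rij, Rc: float = DEFAULT_RC):
    """Cosine cutoff: decays from 1 at R=0 to 0 at R=Rc, zero beyond.

    Accepts scalars or arrays; distances must be non-negative.
    """
    R = np.asarray(Rij, dtype=float)
    if np.any(R < 0):
        raise ValueError("negative interatomic distance")
    if Rc <= 0:
        raise ValueError("Rc must be positive")
    out = np.where(R <= Rc, 0.5 * (np.cos(np.pi * R / Rc) + 1.0), 0.0)
    return float(out) if np.isscalar(Rij) else out


def contribution(Rij, eta: float, Rs: float, Rc: float = DEFAULT_RC):
    """Single-neighbour contribution exp(-eta (R-Rs)^2) * f_c(R)."""
    R = np.asarray(Rij, dtype=float)
    out = np.exp(-eta * (R - Rs) ** 2) * cutoff(R, Rc)
    return float(out) if np.isscalar(Rij) else out


def _shell_grid(params: AEVParams) -> tuple[np.ndarray, np.ndarray]:
    """(Rs, eta) pairs flattened in (Rs-major, eta-minor) order."""
    rs = np.repeat(np.asarray(params.Rs_values, dtype=float), params.K)
    eta = np.tile(np.asarray(params.eta_values, dtype=float), params.L)
    return rs, eta


def compute_radial_aevs(
    ligand_coords: np.ndarray,
    protein: ProteinStructure,
    params: AEVParams = AEVParams(),
) -> np.ndarray:
    """Radial AEVs for every ligand atom: array (n_ligand, N*L*K).

    Untyped protein atoms (type_index -1) never contribute.  Protein atoms
    beyond the cutoff from a given ligand atom contribute exactly zero, so
    pocket pre-filtering is a pure optimisation.  Accumulation uses a fixed
    (atom-index) order for reproducibility.
    """
    lig = np.asarray(ligand_coords, dtype=float).reshape(-1, 3)
    n_lig = lig.shape[0]
    typed = protein.type_index >= 0
    if n_lig == 0:
        return np.zeros((0, params.length))
    out = np.zeros((n_lig, params.n_types, params.n_shells))
    if not np.any(typed):
        return out.reshape(n_lig, params.length)

    pcoords = protein.coords[typed]
    ptypes = protein.type_index[typed]
    # cheap pocket pre-filter: drop atoms beyond Rc of every ligand atom
    d = np.linalg.norm(lig[:, None, :] - pcoords[None, :, :], axis=-1)
    near = (d <= params.Rc).any(axis=0)
    if not np.any(near):
        return out.reshape(n_lig, params.length)
    d = d[:, near]
    ptypes = ptypes[near]

    rs, eta = _shell_grid(params)
    fc = np.where(d <= params.Rc, 0.5 * (np.cos(np.pi * d / params.Rc) + 1.0), 0.0)
    # contributions (n_lig, n_prot, n_shells)
    contrib = np.exp(-eta[None, None, :] * (d[:, :, None] - rs[None, None, :]) ** 2)
    contrib *= fc[:, :, None]
    onehot = np.zeros((ptypes.size, params.n_types))
    onehot[np.arange(ptypes.size), ptypes] = 1.0
    out = np.einsum("ipm,pt->itm", contrib, onehot)
    return out.reshape(n_lig, params.length)


def compute_radial_aev(
    ligand_atom: AtomRecord,
    protein: ProteinStructure,
    params: AEVParams = AEVParams(),
) -> np.ndarray:
    """Radial AEV of one ligand atom (vector of length N*L*K)."""
    return compute_radial_aevs(
        np.asarray(ligand_atom.coords, dtype=float)[None, :], protein, params
    )[0]
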