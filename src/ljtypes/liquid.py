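"""Desk-scale liquid property machinery.

Property definitions (density from mean volume, heat of vaporization from the
gas/liquid potential-energy difference plus RT, dielectric constant from box
dipole fluctuations) plus a minimal rigid-molecule NPT Metropolis Monte Carlo
engine.

This is deliberately a toy stand-in for production MD: molecules are rigid
(single seeded conformer), electrostatics are plainly truncated at the cutoff
(no Ewald), and default system sizes are small. Absolute property accuracy is
NOT the goal; the engine exists so the optimization and model-comparison
machinery can be exercised end to end against a physically sensible backend.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from rdkit.Chem import AllChem

from .chem import MoleculeGraph, TypingModel, assign_types
from .core import AVOGADRO, COULOMB_KCAL, KCAL_TO_KJ, LJParameterSet, R_KJ

R_KCAL = R_KJ / KCAL_TO_KJ  # kcal/(mol K)
#: P[atm] * V[A^3] -> kcal/mol
ATM_A3_TO_KCAL = 101325.0 * 1e-30 * AVOGADRO / 4184.0
#: (e*A)^2 / (eps0 * A^3 * k_B) in K, for the dielectric fluctuation formula
_DIPOLE_FACTOR = (1.602176634e-19 * 1e-10) ** 2 / (
    8.8541878128e-12 * 1e-30 * 1.380649e-23
)


class ConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """NPT Monte Carlo settings (defaults are desk scale, not production)."""

    temperature: float = 298.0  # K
    pressure: float = 1.0  # atm
    n_molecules: int = 100
    cutoff: float = 9.0  # Angstrom
    n_equil_moves: int = 200_000
    n_prod_moves: int = 1_000_000
    seed: int = 0
    volume_interval_sweeps: int = 25  # volume-move attempt every N particle sweeps
    sample_interval: int = 100  # moves between samples in production
    max_translation: float = 0.35  # Angstrom
    max_rotation: float = 0.35  # radians
    max_ln_volume: float = 0.02
    initial_density: float = 600.0  # kg/m^3 starting guess

    def __post_init__(self):
        if self.temperature <= 0 or self.pressure <= 0:
            raise ConfigError("temperature and pressure must be positive")


@dataclass
class LiquidObservables:
    mean_volume: float  # A^3
    se_volume: float
    mean_u_per_molecule: float  # kJ/mol, includes constant intramolecular part
    se_u_per_molecule: float
    dipole_samples: np.ndarray  # (n_samples, 3), e*A
    n_samples: int
    acceptance: float


@dataclass
class GasObservables:
    mean_u: float  # kJ/mol
    se_u: float


# --------------------------------------------------------------------------
# Property definitions
# --------------------------------------------------------------------------

def density_from_volume(mean_volume: float, n: int, molar_mass: float) -> float:
    """Mass density in kg/m^3 from a mean box volume in A^3."""
    if mean_volume <= 0:
        raise ValueError("volume must be positive")
    if n == 0:
        return 0.0
    return n * molar_mass * 1e27 / (AVOGADRO * mean_volume)


def heat_of_vaporization(u_gas: float, u_liq_per_mol: float, temperature: float) -> float:
    """HOV = u_gas - u_liq + RT, all in kJ/mol."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return u_gas - u_liq_per_mol + R_KJ * temperature


def dielectric_from_dipoles(
    dipole_samples: np.ndarray,
    mean_volume: float,
    temperature: float,
    subtract_mean: bool = True,
) -> float:
    """Relative permittivity from box-dipole fluctuations.

    eps_r = 1 + (<M^2> - <M>.<M>) / (3 eps0 V k_B T), conducting-boundary
    form; ``subtract_mean=False`` drops the <M> term.
    Dipoles in e*A, volume in A^3.
    """
    samples = np.asarray(dipole_samples, dtype=float)
    if samples.ndim != 2 or samples.shape[0] < 2:
        raise ValueError("need at least 2 dipole samples")
    m2 = float(np.mean(np.sum(samples**2, axis=1)))
    if subtract_mean:
        mean = samples.mean(axis=0)
        m2 -= float(mean @ mean)
    return 1.0 + _DIPOLE_FACTOR * m2 / (3.0 * mean_volume * temperature)


def metropolis(delta_w: float, rng: np.random.Generator) -> bool:
    """Accept a move with weight exp(-delta_w); downhill always accepted."""
    if delta_w <= 0:
        return True
    return rng.random() < math.exp(-min(delta_w, 700.0))


# --------------------------------------------------------------------------
# Rigid-molecule geometry
# --------------------------------------------------------------------------

def molecule_geometry(mol: MoleculeGraph, seed: int = 0) -> np.ndarray:
    """A single embedded conformer, centered on its center of geometry (A)."""
    m = AllChem.Mol(mol.mol)
    if m.GetNumAtoms() == 1:
        return np.zeros((1, 3))
    if AllChem.EmbedMolecule(m, randomSeed=seed + 1, useRandomCoords=False) != 0:
        if AllChem.EmbedMolecule(m, randomSeed=seed + 1, useRandomCoords=True) != 0:
            raise ValueError(f"could not embed geometry for {mol.smiles!r}")
    coords = np.array(m.GetConformer().GetPositions(), dtype=float)
    return coords - coords.mean(axis=0)


def _bond_distance_le2(mol: MoleculeGraph) -> np.ndarray:
    """Boolean (na, na) mask: True where bond-graph distance <= 2 (excluded)."""
    na = mol.n_atoms
    adj = np.zeros((na, na), dtype=bool)
    for i, j in mol.bonds:
        adj[i, j] = adj[j, i] = True
    two = adj @ adj
    excl = adj | (two > 0)
    np.fill_diagonal(excl, True)
    return excl


# --------------------------------------------------------------------------
# NPT Monte Carlo engine
# --------------------------------------------------------------------------

class ToyLiquid:
    """Rigid-molecule NPT Metropolis MC of n identical molecules.

    Energy model: minimum-image 12-6 LJ (Lorentz-Berthelot per-atom
    parameters) + truncated Coulomb within the cutoff, plus the standard
    analytic LJ tail correction. All intramolecular interactions are constant
    (rigid bodies) and excluded from the running energy.
    """

    def __init__(
        self,
        mol: MoleculeGraph,
        params: LJParameterSet,
        model: TypingModel,
        cfg: SimConfig,
    ):
        self.cfg = cfg
        self.mol = mol
        self.rng = np.random.default_rng(cfg.seed)
        type_ids = assign_types(mol, model)
        eps = np.array([params.get(t).epsilon for t in type_ids])
        rmh = np.array([params.get(t).rmin_half for t in type_ids])
        q = np.array([mol.charge(i) for i in range(mol.n_atoms)])
        self.eps_pair = np.sqrt(np.outer(eps, eps))
        self.rmin_pair = rmh[:, None] + rmh[None, :]
        self.qq_pair = COULOMB_KCAL * np.outer(q, q)
        self.is_ideal = bool(np.all(eps == 0) and np.all(q == 0))

        self.template = molecule_geometry(mol, seed=cfg.seed)
        self.n = cfg.n_molecules
        self.na = mol.n_atoms
        self.beta = 1.0 / (R_KCAL * cfg.temperature)

        # constant intramolecular energy over pairs > 2 bonds apart (kcal/mol)
        excl = _bond_distance_le2(mol)
        iu = np.triu_indices(self.na, k=1)
        keep = ~excl[iu]
        d = self.template[iu[0][keep]] - self.template[iu[1][keep]]
        r = np.linalg.norm(d, axis=1)
        x6 = (self.rmin_pair[iu][keep] / r) ** 6
        self.u_intra = float(
            np.sum(self.eps_pair[iu][keep] * (x6 * x6 - 2 * x6))
            + np.sum(self.qq_pair[iu][keep] / r)
        )

        # LJ tail integral per ordered molecule pair: sum over atom pairs of
        # eps*(rmin^12/(9 rc^9) - 2 rmin^6/(3 rc^3))
        rc = cfg.cutoff
        self._tail_mol = float(
            np.sum(
                self.eps_pair
                * (self.rmin_pair**12 / (9 * rc**9) - 2 * self.rmin_pair**6 / (3 * rc**3))
            )
        )

        self._init_lattice()
        if cfg.cutoff >= self.box_edge / 2:
            raise ConfigError(
                f"cutoff {cfg.cutoff} A must be below half the box edge "
                f"({self.box_edge / 2:.2f} A)"
            )
        self.u_inter = self.total_inter_energy()

    # -- setup ------------------------------------------------------------

    def _init_lattice(self):
        cfg = self.cfg
        volume = self.n * self.mol.molar_mass * 1e27 / (AVOGADRO * cfg.initial_density)
        self.box_edge = volume ** (1.0 / 3.0)
        ncell = math.ceil(self.n ** (1.0 / 3.0))
        spacing = self.box_edge / ncell
        coords = np.empty((self.n, self.na, 3))
        coms = np.empty((self.n, 3))
        i = 0
        for a in range(ncell):
            for b in range(ncell):
                for c in range(ncell):
                    if i >= self.n:
                        break
                    com = (np.array([a, b, c]) + 0.5) * spacing
                    rot = self._random_rotation()
                    coords[i] = com + self.template @ rot.T
                    coms[i] = com
                    i += 1
        self.coords = coords
        self.coms = coms

    def _random_rotation(self) -> np.ndarray:
        # uniform random rotation via normalized quaternion
        u = self.rng.normal(size=4)
        w, x, y, z = u / np.linalg.norm(u)
        return np.array(
            [
                [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
                [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
                [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
            ]
        )

    # -- energies (kcal/mol) ----------------------------------------------

    @property
    def volume(self) -> float:
        return self.box_edge**3

    def tail_energy(self, volume: float | None = None) -> float:
        v = self.volume if volume is None else volume
        return 2.0 * math.pi * self.n**2 * self._tail_mol / v

    def _pair_block_energy(self, xi: np.ndarray, others: np.ndarray, edge: float) -> float:
        """Energy of one molecule's atoms (na,3) vs a stack (m,na,3)."""
        if others.size == 0:
            return 0.0
        d = others[:, :, None, :] - xi[None, None, :, :]
        d -= edge * np.round(d / edge)
        r2 = np.einsum("mijk,mijk->mij", d, d)
        np.maximum(r2, 1e-12, out=r2)  # overlaps -> huge repulsion, not inf
        within = r2 < self.cfg.cutoff**2
        x6 = np.where(within, (self.rmin_pair[None] ** 2 / r2) ** 3, 0.0)
        e_lj = np.sum(self.eps_pair[None] * (x6 * x6 - 2 * x6))
        e_c = np.sum(np.where(within, self.qq_pair[None] / np.sqrt(r2), 0.0))
        return float(e_lj + e_c)

    def molecule_energy(self, i: int, coords: np.ndarray | None = None) -> float:
        """Interaction of molecule i with all other molecules (no tail)."""
        if self.is_ideal:
            return 0.0
        xs = self.coords if coords is None else coords
        others = np.delete(xs, i, axis=0)
        return self._pair_block_energy(xs[i], others, self.box_edge)

    def total_inter_energy(self, coords: np.ndarray | None = None, edge: float | None = None) -> float:
        """Full recomputation of the intermolecular energy (no tail)."""
        if self.is_ideal:
            return 0.0
        xs = self.coords if coords is None else coords
        L = self.box_edge if edge is None else edge
        total = 0.0
        for i in range(self.n - 1):
            total += self._pair_block_energy(xs[i], xs[i + 1 :], L)
        return total

    # -- moves -------------------------------------------------------------

    def particle_move(self) -> bool:
        cfg = self.cfg
        i = int(self.rng.integers(self.n))
        old_e = self.molecule_energy(i)
        old_coords = self.coords[i].copy()
        old_com = self.coms[i].copy()

        shift = self.rng.uniform(-cfg.max_translation, cfg.max_translation, 3)
        angle_axis = self.rng.normal(size=3)
        angle = self.rng.uniform(-cfg.max_rotation, cfg.max_rotation)
        rot = _axis_angle(angle_axis, angle)
        new_com = old_com + shift
        self.coords[i] = new_com + (old_coords - old_com) @ rot.T
        self.coms[i] = new_com

        new_e = self.molecule_energy(i)
        if metropolis(self.beta * (new_e - old_e), self.rng):
            self.u_inter += new_e - old_e
            return True
        self.coords[i] = old_coords
        self.coms[i] = old_com
        return False

    def volume_move(self) -> bool:
        cfg = self.cfg
        v_old = self.volume
        ln_new = math.log(v_old) + self.rng.uniform(-cfg.max_ln_volume, cfg.max_ln_volume)
        v_new = math.exp(ln_new)
        edge_new = v_new ** (1.0 / 3.0)
        if cfg.cutoff >= edge_new / 2:
            return False
        s = edge_new / self.box_edge
        new_coms = self.coms * s
        new_coords = self.coords + (new_coms - self.coms)[:, None, :]
        u_new = self.total_inter_energy(new_coords, edge_new)
        du = (u_new + self.tail_energy(v_new)) - (self.u_inter + self.tail_energy(v_old))
        dw = self.beta * (
            du + cfg.pressure * ATM_A3_TO_KCAL * (v_new - v_old)
        ) - (self.n + 1) * math.log(v_new / v_old)
        if metropolis(dw, self.rng):
            self.coords = new_coords
            self.coms = new_coms
            self.box_edge = edge_new
            self.u_inter = u_new
            return True
        return False

    # -- sampling ----------------------------------------------------------

    def box_dipole(self) -> np.ndarray:
        """Total dipole moment in e*A (charges times absolute positions)."""
        charges = np.array([self.mol.charge(i) for i in range(self.na)])
        return np.einsum("a,mak->k", charges, self.coords)

    def run(self, n_moves: int, sample_interval: int | None = None):
        """Run n_moves particle moves with interleaved volume moves; returns
        (volumes, energies, dipoles, acceptance) sampled every interval."""
        cfg = self.cfg
        interval = sample_interval or cfg.sample_interval
        vol_every = max(1, cfg.volume_interval_sweeps * self.n)
        vols, energies, dipoles = [], [], []
        accepted = 0
        for step in range(1, n_moves + 1):
            accepted += self.particle_move()
            if step % vol_every == 0:
                self.volume_move()
            if step % interval == 0:
                vols.append(self.volume)
                energies.append(self.u_inter + self.tail_energy())
                dipoles.append(self.box_dipole())
        return (
            np.array(vols),
            np.array(energies),
            np.array(dipoles) if dipoles else np.zeros((0, 3)),
            accepted / max(n_moves, 1),
        )


def _axis_angle(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        return np.eye(3)
    x, y, z = axis / norm
    c, s = math.cos(angle), math.sin(angle)
    C = 1 - c
    return np.array(
        [
            [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
            [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
            [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
        ]
    )


def _block_se(samples: np.ndarray, n_blocks: int = 20) -> float:
    """Standard error by block averaging (guards against correlation)."""
    samples = np.asarray(samples, dtype=float)
    if samples.size < 2:
        return float("inf")
    nb = min(n_blocks, samples.size)
    blocks = np.array_split(samples, nb)
    means = np.array([b.mean() for b in blocks])
    return float(means.std(ddof=1) / math.sqrt(nb))


def run_toy_liquid(
    mol: MoleculeGraph,
    params: LJParameterSet,
    model: TypingModel,
    cfg: SimConfig,
) -> tuple[LiquidObservables, GasObservables]:
    """Equilibrate and sample the toy NPT liquid; deterministic given the seed.

    Liquid potential energies are reported per molecule in kJ/mol, including
    the constant intramolecular contribution, so that
    ``heat_of_vaporization(gas.mean_u, liq.mean_u_per_molecule, T)`` follows
    the gas-minus-liquid-plus-RT definition.
    """
    system = ToyLiquid(mol, params, model, cfg)
    system.run(cfg.n_equil_moves)
    vols, energies, dipoles, acc = system.run(cfg.n_prod_moves)
    if vols.size == 0:
        raise ConfigError("production run produced no samples")
    u_per_mol_kcal = energies / system.n + system.u_intra
    liquid = LiquidObservables(
        mean_volume=float(vols.mean()),
        se_volume=_block_se(vols),
        mean_u_per_molecule=float(u_per_mol_kcal.mean()) * KCAL_TO_KJ,
        se_u_per_molecule=_block_se(u_per_mol_kcal) * KCAL_TO_KJ,
        dipole_samples=dipoles,
        n_samples=int(vols.size),
        acceptance=acc,
    )
    # rigid single conformer: the gas-phase energy has zero variance
    gas = GasObservables(mean_u=system.u_intra * KCAL_TO_KJ, se_u=0.0)
    return liquid, gas


def liquid_properties(
    mol: MoleculeGraph,
    params: LJParameterSet,
    model: TypingModel,
    cfg: SimConfig,
    subtract_mean_dipole: bool = True,
) -> dict[str, float]:
    """Density (kg/m^3), HOV (kJ/mol) and dielectric from a toy NPT run."""
    liquid, gas = run_toy_liquid(mol, params, model, cfg)
    return {
        "density": density_from_volume(
            liquid.mean_volume, cfg.n_molecules, mol.molar_mass
        ),
        "hov": heat_of_vaporization(
            gas.mean_u, liquid.mean_u_per_molecule, cfg.temperature
        ),
        "dielectric": dielectric_from_dipoles(
            liquid.dipole_samples,
            liquid.mean_volume,
            cfg.temperature,
            subtract_mean=subtract_mean_dipole,
        ),
    }
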