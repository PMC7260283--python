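"""Synthetic inputs with known ground truth.

Three generators stand in for the raw measurements of the study design:

* photon-counting luminescence decays — Poisson-noised sums of
  exponentials with a constant background, including the fast
  instrument-artifact component seen in gated Tb3+ detection;
* iodide quench titrations — hyperbolic intensity decrease
  F = F0/(1 + K_SV [Q]) with Gaussian readout noise and per-step dilution;
* tethered-chain conformational ensembles — a freely-jointed chain of
  0.38 nm virtual Cα–Cα bonds anchored to a fixed point, sampled either
  freely (the disordered, inward-facing N-terminus) or with one residue
  harmonically restrained to a site (the salt-bridge-locked outward
  state), optionally excluded from a membrane half-space or a micelle
  sphere.

The freely-jointed chain is the minimal model of a disordered peptide and
brings closed-form statistics (<R^2> = N b^2) that serve as oracles for
recovery tests.  All generators take explicit seeds; no global random
state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from biotite.structure import AtomArray, AtomArrayStack
from biotite.structure.io.pdb import PDBFile

from .ensemble import StructuralEnsemble
from .lret import DecayTrace
from .quenching import QuenchTitration

#: Cα–Cα virtual bond length of a polypeptide, nm
CA_BOND_LENGTH = 0.38


@dataclass
class DecayParams:
    """Ground truth for a simulated luminescence decay."""

    lifetimes: tuple[float, ...]  # ms, strictly positive, unique
    amplitudes: tuple[float, ...]  # counts, non-negative
    background: float = 0.0  # counts
    time_grid: tuple[float, float, float] = (0.0, 10.0, 0.005)  # start/stop/step ms
    noise: str = "poisson"  # {"none", "poisson"}
    seed: int = 0

    def __post_init__(self) -> None:
        self.lifetimes = tuple(float(t) for t in self.lifetimes)
        self.amplitudes = tuple(float(a) for a in self.amplitudes)
        if not self.lifetimes:
            raise ValueError("at least one lifetime is required")
        if len(self.lifetimes) != len(self.amplitudes):
            raise ValueError("lifetimes and amplitudes must have equal length")
        if any(t <= 0 for t in self.lifetimes):
            raise ValueError("lifetimes must be strictly positive")
        if len(set(self.lifetimes)) != len(self.lifetimes):
            raise ValueError("lifetimes must be unique")
        if any(a < 0 for a in self.amplitudes):
            raise ValueError("amplitudes must be non-negative")
        if self.background < 0:
            raise ValueError("background must be non-negative")
        start, stop, step = self.time_grid
        if step <= 0 or stop <= start:
            raise ValueError("time grid must have positive step and stop > start")
        if self.noise not in ("none", "poisson"):
            raise ValueError(f"unknown noise model {self.noise!r}")


def simulate_decay(params: DecayParams) -> DecayTrace:
    """Simulate a decay trace; Poisson noise is reproducible under seed.

    Noiseless counts at time t are background + sum_k a_k exp(-t/tau_k);
    with ``noise="poisson"`` each point is an integer Poisson draw with
    that mean, emulating photon counting.
    """
    start, stop, step = params.time_grid
    times = np.arange(start, stop + 0.5 * step, step)
    mean = np.full_like(times, params.background, dtype=float)
    for a, tau in zip(params.amplitudes, params.lifetimes):
        mean += a * np.exp(-times / tau)
    if params.noise == "poisson":
        counts = np.random.default_rng(params.seed).poisson(mean).astype(float)
    else:
        counts = mean
    return DecayTrace(
        times=times,
        counts=counts,
        metadata={"params": params},
    )


def simulate_quench_titration(
    F0: float,
    KSV: float,
    concentrations,
    noise_sd: float = 0.0,
    seed: int = 0,
    dilution_per_step: float = 1.0,
) -> QuenchTitration:
    """Simulate a Stern–Volmer titration with optional Gaussian noise.

    The noiseless intensity follows F = F0 / (1 + K_SV [Q]).  Adding
    quencher aliquots dilutes the sample; the simulated raw readings are
    divided by the cumulative dilution factor and the stored F values are
    the dilution-corrected ones, as an analysis would produce.  The
    titration's F0 is the (possibly noisy) measured zero-quencher point.
    """
    concentrations = np.asarray(list(concentrations), dtype=float)
    if concentrations.size == 0:
        raise ValueError("no concentrations given")
    if np.any(concentrations < 0):
        raise ValueError("concentrations must be non-negative")
    if np.any(np.diff(concentrations) < 0):
        raise ValueError("concentrations must be ascending")
    if F0 <= 0:
        raise ValueError("F0 must be positive")
    if dilution_per_step < 1:
        raise ValueError("dilution_per_step must be >= 1")
    rng = np.random.default_rng(seed)
    ideal = F0 / (1.0 + KSV * concentrations)
    if noise_sd > 0:
        ideal = ideal + rng.normal(0.0, noise_sd, size=ideal.shape)
    if np.any(ideal <= 0):
        raise ValueError("noise drove an intensity non-positive; lower noise_sd")
    return QuenchTitration(
        concentrations=concentrations, F=ideal, F0=float(ideal[0])
    )


@dataclass
class ChainSpec:
    """Parameters of the tethered freely-jointed chain.

    ``n_residues`` mobile beads hang off a fixed anchor via bonds of
    ``bond_length`` nm.  In ``outward_locked`` mode the bead at
    ``restraint_residue`` (default 5, the salt-bridge position) is
    harmonically restrained to ``restraint_site`` with force constant
    ``restraint_k`` in kT/nm^2, so its thermal per-axis sd is
    1/sqrt(restraint_k) nm.  The membrane is the half-space z < slab_z
    (beads must stay at z >= slab_z); the micelle is an excluded sphere.
    An optional static ``reference_site`` bead is appended so distance
    distributions to a remote residue (the A335/H510 analogue) can be
    measured on the synthetic ensemble.
    """

    n_residues: int
    bond_length: float = CA_BOND_LENGTH  # nm
    anchor: tuple[float, float, float] = (0.0, 0.0, 0.0)
    mode: str = "inward_free"  # {"inward_free", "outward_locked"}
    environment: str = "none"  # {"none", "membrane", "micelle"}
    restraint_site: tuple[float, float, float] | None = None
    restraint_k: float = 0.0  # kT/nm^2
    restraint_residue: int = 5
    slab_z: float | None = None  # nm, membrane plane
    micelle_center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    micelle_radius: float | None = None  # nm
    reference_site: tuple[float, float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 1:
            raise ValueError("n_residues must be >= 1")
        if self.bond_length <= 0:
            raise ValueError("bond_length must be positive")
        if self.mode not in ("inward_free", "outward_locked"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.environment not in ("none", "membrane", "micelle"):
            raise ValueError(f"unknown environment {self.environment!r}")
        if self.environment == "membrane":
            if self.slab_z is None:
                raise ValueError("membrane environment requires slab_z")
            if self.anchor[2] < self.slab_z:
                raise ValueError("infeasible geometry: anchor below membrane plane")
        if self.environment == "micelle":
            if self.micelle_radius is None or self.micelle_radius <= 0:
                raise ValueError("micelle environment requires a positive radius")
            if (
                np.linalg.norm(np.subtract(self.anchor, self.micelle_center))
                < self.micelle_radius
            ):
                raise ValueError("infeasible geometry: anchor inside micelle")
        if self.mode == "outward_locked":
            if self.restraint_site is None or self.restraint_k <= 0:
                raise ValueError(
                    "outward_locked mode requires restraint_site and restraint_k > 0"
                )
            m = min(self.restraint_residue, self.n_residues)
            reach = m * self.bond_length
            d = np.linalg.norm(np.subtract(self.restraint_site, self.anchor))
            if d > reach:
                raise ValueError(
                    f"infeasible geometry: restraint site {d:.3f} nm from anchor "
                    f"exceeds chain reach {reach:.3f} nm"
                )


def _random_unit(rng, shape) -> np.ndarray:
    v = rng.normal(size=shape + (3,))
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def _violates(positions: np.ndarray, spec: ChainSpec) -> bool:
    """Hard-wall check on a (n_beads, 3) position array."""
    if spec.environment == "membrane":
        return bool(np.any(positions[:, 2] < spec.slab_z))
    if spec.environment == "micelle":
        d = np.linalg.norm(positions - np.asarray(spec.micelle_center), axis=1)
        return bool(np.any(d < spec.micelle_radius))
    return False


def _batch_valid(positions: np.ndarray, spec: ChainSpec) -> np.ndarray:
    """Vectorized wall check on (n_frames, n_beads, 3); True = keep."""
    if spec.environment == "membrane":
        return np.all(positions[:, :, 2] >= spec.slab_z, axis=1)
    if spec.environment == "micelle":
        d = np.linalg.norm(
            positions - np.asarray(spec.micelle_center), axis=2
        )
        return np.all(d >= spec.micelle_radius, axis=1)
    return np.ones(positions.shape[0], dtype=bool)


def _initial_bonds(spec: ChainSpec, rng) -> np.ndarray:
    """A wall-respecting start with the restrained bead at its site."""
    n, b = spec.n_residues, spec.bond_length
    anchor = np.asarray(spec.anchor, dtype=float)
    bonds = np.zeros((n, 3))
    m = min(spec.restraint_residue, n)
    target = np.asarray(spec.restraint_site, dtype=float) - anchor
    d = np.linalg.norm(target)
    u = target / d if d > 0 else np.array([0.0, 0.0, 1.0])
    # zig-zag construction: each of the first m bonds advances d/m along u
    perp = np.cross(u, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-8:
        perp = np.cross(u, [1.0, 0.0, 0.0])
    perp /= np.linalg.norm(perp)
    along = d / m
    across = np.sqrt(max(b**2 - along**2, 0.0))
    for j in range(m):
        bonds[j] = along * u + ((-1) ** j) * across * perp
    # odd leftover zig: fold the last bond to land exactly on the target
    pos = anchor + bonds[:m].cumsum(axis=0)[-1]
    bonds[m - 1] += np.asarray(spec.restraint_site) - pos
    norm = np.linalg.norm(bonds[m - 1])
    if norm > 0:
        bonds[m - 1] *= b / norm
    # remaining bonds: greedy sampling that respects the walls
    pos = anchor + bonds[:m].sum(axis=0)
    for j in range(m, n):
        for _ in range(200):
            step = _random_unit(rng, ()) * b
            cand = pos + step
            if not _violates(cand[None, :], spec):
                break
        else:  # point away from the obstacle as a last resort
            if spec.environment == "membrane":
                step = np.array([0.0, 0.0, b])
            else:
                out = pos - np.asarray(spec.micelle_center)
                step = b * out / np.linalg.norm(out)
        bonds[j] = step
        pos = anchor + bonds[: j + 1].sum(axis=0)
    return bonds


def _sample_locked(spec: ChainSpec, n_frames: int, rng) -> np.ndarray:
    """Metropolis sampling of the restrained chain.

    The target density is the freely-jointed prior times the Boltzmann
    factor exp(-k/2 |x_m - site|^2) with hard walls.  Moves redraw one
    bond direction, either from the uniform sphere or by a small angular
    perturbation (both proposals are symmetric), and frames are collected
    after burn-in with thinning, so successive frames are effectively
    decorrelated rather than strictly independent.
    """
    n, b = spec.n_residues, spec.bond_length
    anchor = np.asarray(spec.anchor, dtype=float)
    site = np.asarray(spec.restraint_site, dtype=float)
    k = spec.restraint_k
    m = min(spec.restraint_residue, n)

    bonds = _initial_bonds(spec, rng)
    positions = anchor + np.cumsum(bonds, axis=0)

    def energy(pos_m: np.ndarray) -> float:
        return 0.5 * k * float(np.sum((pos_m - site) ** 2))

    e_cur = energy(positions[m - 1])
    burn_in = 200 * n
    thin = 10 * n
    total = burn_in + thin * n_frames

    # pre-draw the per-move randomness in blocks for speed
    idx_all = rng.integers(0, n, size=total)
    kind_all = rng.random(total) < 0.3  # True -> full redraw
    unit_all = _random_unit(rng, (total,))
    gauss_all = rng.normal(scale=0.3, size=(total, 3))
    accept_all = rng.random(total)

    frames = np.empty((n_frames, n, 3))
    collected = 0
    next_collect = burn_in
    for t in range(total):
        j = idx_all[t]
        old = bonds[j]
        if kind_all[t]:
            new = unit_all[t] * b
        else:
            v = old + gauss_all[t] * b
            new = v * (b / np.linalg.norm(v))
        delta = new - old
        if j < m:
            e_new = energy(positions[m - 1] + delta)
            d_e = e_new - e_cur
        else:
            d_e = 0.0
        if d_e <= 0 or accept_all[t] < np.exp(-d_e):
            trial = positions.copy()
            trial[j:] += delta
            if not _violates(trial, spec):
                bonds[j] = new
                positions = trial
                if j < m:
                    e_cur = e_cur + d_e
        if t + 1 == next_collect and collected < n_frames:
            frames[collected] = positions
            collected += 1
            next_collect += thin
    return frames


def _sample_free(spec: ChainSpec, n_frames: int, rng) -> np.ndarray:
    """Direct sampling with rejection; Metropolis fallback if walls are
    so restrictive that fewer than 1 in 1000 draws survive."""
    n, b = spec.n_residues, spec.bond_length
    anchor = np.asarray(spec.anchor, dtype=float)
    kept = []
    n_drawn = 0
    n_kept = 0
    while n_kept < n_frames:
        batch = max(n_frames - n_kept, 1000)
        bonds = _random_unit(rng, (batch, n)) * b
        positions = anchor + np.cumsum(bonds, axis=1)
        good = _batch_valid(positions, spec)
        kept.append(positions[good])
        n_drawn += batch
        n_kept += int(good.sum())
        if n_drawn >= 200_000 and n_kept / n_drawn < 1e-3:
            # acceptance below the 0.999-rejection threshold: fall back
            fallback = ChainSpec(
                n_residues=n,
                bond_length=b,
                anchor=spec.anchor,
                mode="outward_locked",
                environment=spec.environment,
                restraint_site=tuple(anchor + [0, 0, 1e-6]),
                restraint_k=1e-12,  # vanishing restraint: plain hard walls
                restraint_residue=n,
                slab_z=spec.slab_z,
                micelle_center=spec.micelle_center,
                micelle_radius=spec.micelle_radius,
            )
            return _sample_locked(fallback, n_frames, rng)
    return np.concatenate(kept, axis=0)[:n_frames]


def sample_tethered_chain(spec: ChainSpec, n_frames: int) -> StructuralEnsemble:
    """Draw an ensemble of tethered-chain conformations.

    Residues 1..n are the mobile beads in chain order; the anchor point is
    appended as a static bead with residue id n+1, and, when
    ``reference_site`` is set, a static reference bead with id n+2.
    Bit-reproducible for a fixed (spec, n_frames).
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(spec.seed)
    if spec.mode == "outward_locked":
        mobile = _sample_locked(spec, n_frames, rng)
    else:
        mobile = _sample_free(spec, n_frames, rng)

    extras = [np.asarray(spec.anchor, dtype=float)]
    names = ["ALA"] * spec.n_residues + ["ANC"]
    if spec.reference_site is not None:
        extras.append(np.asarray(spec.reference_site, dtype=float))
        names.append("REF")
    static = np.broadcast_to(
        np.stack(extras), (n_frames, len(extras), 3)
    )
    frames = np.concatenate([mobile, static], axis=1)
    return StructuralEnsemble(
        frames=frames,
        residue_ids=np.arange(1, frames.shape[1] + 1),
        residue_names=tuple(names),
        labels=(spec.mode,) * n_frames,
    )


def write_ensemble_pdb(ensemble: StructuralEnsemble, path) -> None:
    """Write a multi-model PDB, one MODEL per frame, coordinates in Å."""
    if ensemble.n_frames == 0 or ensemble.n_residues == 0:
        raise ValueError("cannot write an empty ensemble")
    if not np.all(np.isfinite(ensemble.frames)):
        raise ValueError("non-finite coordinates in ensemble")
    n_res = ensemble.n_residues
    template = AtomArray(n_res)
    template.chain_id[:] = ensemble.chain
    template.res_id[:] = ensemble.residue_ids
    names = ensemble.residue_names or ("ALA",) * n_res
    template.res_name[:] = list(names)
    template.atom_name[:] = "CA"
    template.element[:] = "C"
    template.hetero[:] = False
    stack = AtomArrayStack(ensemble.n_frames, n_res)
    for cat in template.get_annotation_categories():
        stack.set_annotation(cat, template.get_annotation(cat))
    stack.coord = ensemble.frames * 10.0  # nm -> Å
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))
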