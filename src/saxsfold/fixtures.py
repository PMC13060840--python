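"""Deterministic synthetic structures, ensembles, and profiles.

Every other module is exercisable without downloading anything: these
generators produce CA-trace chains (helix, extended, collapsed globule),
rigid two-domain hinge pairs standing in for apo-holo conformer pairs,
multi-model "NMR" ensembles, and noisy experimental-style scattering
profiles.  All outputs are pure functions of (spec, seed).

Geometry: consecutive CA atoms sit 3.8 A apart (plus any requested noise).
The helix uses a 1.5 A rise, 100 degrees per residue, and 2.3 A radius —
standard alpha-helical CA parameters; the extended chain uses a 3.5 A rise
with a lateral zigzag restoring the 3.8 A virtual bond.  CA-only fixtures
carry a placeholder electron count of 6 per residue.

What these fixtures do NOT emulate: side chains, secondary-structure
packing, solvent, or realistic NMR restraint geometry.  They give the right
kind of P(r) and RMSD behaviour (compact vs expanded, small vs large
conformational change), not physically relaxed proteins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError
from .profile import ScatteringProfile, debye_intensity
from .structures import AtomicStructure, ConformerEnsemble, pseudo_sequence

HELIX_RISE = 1.5       # Angstrom per residue
HELIX_TWIST = 100.0    # degrees per residue
HELIX_RADIUS = 2.3     # Angstrom
EXTENDED_RISE = 3.5    # Angstrom per residue
CA_STEP = 3.8          # Angstrom, consecutive-CA distance


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic structure family."""

    kind: str = "helix"        # helix | extended | globule | hinge_pair | nmr_ensemble
    n_residues: int = 64
    noise: float = 0.0         # Angstrom, iid Gaussian on coordinates
    hinge_angle: float = 90.0  # degrees, hinge opening of the second conformer
    globule_radius: float = 12.0
    n_models: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 2:
            raise InvalidParameterError("need at least two residues")
        if self.noise < 0:
            raise InvalidParameterError("noise must be non-negative")


def _helix_coords(n: int) -> np.ndarray:
    t = np.arange(n)
    ang = np.radians(HELIX_TWIST) * t
    return np.stack([
        HELIX_RADIUS * np.cos(ang),
        HELIX_RADIUS * np.sin(ang),
        HELIX_RISE * t,
    ], axis=1)


def _extended_coords(n: int) -> np.ndarray:
    # zigzag amplitude restoring the 3.8 A step at a 3.5 A rise
    amp = 0.5 * math.sqrt(CA_STEP ** 2 - EXTENDED_RISE ** 2)
    t = np.arange(n)
    return np.stack([
        amp * (-1.0) ** t,
        np.zeros(n),
        EXTENDED_RISE * t,
    ], axis=1)


def _globule_coords(n: int, radius: float, rng: np.random.Generator) -> np.ndarray:
    """Self-avoiding-ish random walk of 3.8 A steps reflected into a sphere."""
    coords = np.zeros((n, 3))
    for i in range(1, n):
        step = rng.standard_normal(3)
        step *= CA_STEP / np.linalg.norm(step)
        nxt = coords[i - 1] + step
        r = np.linalg.norm(nxt)
        if r > radius:   # reflect back toward the centre
            nxt = coords[i - 1] - step
        coords[i] = nxt
    return coords


def make_chain(spec: FixtureSpec) -> AtomicStructure:
    """One CA-trace chain of the requested geometry."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_residues
    if spec.kind == "helix":
        coords = _helix_coords(n)
    elif spec.kind == "extended":
        coords = _extended_coords(n)
    elif spec.kind == "globule":
        coords = _globule_coords(n, spec.globule_radius, rng)
    else:
        raise InvalidParameterError(f"make_chain cannot build kind {spec.kind!r}")
    if spec.noise > 0:
        coords = coords + rng.normal(0.0, spec.noise, coords.shape)
    return AtomicStructure.from_ca(coords, sequence=pseudo_sequence(n, spec.seed))


def make_hinge_pair(spec: FixtureSpec) -> tuple[AtomicStructure, AtomicStructure]:
    """Two conformers of one sequence differing only by a rigid hinge rotation.

    The chain has two straight 3.8 A-step arms joined at the midpoint; the
    open conformer is fully extended (arms collinear) while the closed
    conformer bends the second arm by ``hinge_angle`` about the hinge.  Pair
    RMSD grows monotonically with the hinge angle, and the open state has
    the larger maximum extent.
    """
    n = spec.n_residues
    half = n // 2
    seq = pseudo_sequence(n, spec.seed)
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, spec.noise, (n, 3)) if spec.noise > 0 else 0.0

    def build(angle_deg: float) -> AtomicStructure:
        coords = np.zeros((n, 3))
        # first arm along -x ending at the origin (the hinge)
        for i in range(half):
            coords[i] = [-(half - 1 - i) * CA_STEP, 0.0, 0.0]
        theta = math.radians(angle_deg)
        direction = np.array([math.cos(theta), math.sin(theta), 0.0])
        for j in range(half, n):
            coords[j] = coords[half - 1] + direction * CA_STEP * (j - half + 1)
        return AtomicStructure.from_ca(coords + noise, sequence=seq)

    open_state = build(0.0)
    closed = build(spec.hinge_angle)
    return open_state, closed


def make_nmr_ensemble(spec: FixtureSpec) -> ConformerEnsemble:
    """A multi-model ensemble: one base chain plus per-model perturbations.

    Emulates the 20-30 alternative conformers of a solution NMR deposition:
    every model shares the sequence and numbering; coordinates differ by
    smooth low-frequency displacements plus iid noise so that intra-ensemble
    RMSD grows with the requested noise amplitude.
    """
    base_spec = FixtureSpec(kind="helix", n_residues=spec.n_residues, seed=spec.seed)
    base = make_chain(base_spec)
    rng = np.random.default_rng(spec.seed)
    n = spec.n_residues
    t = np.linspace(0.0, 1.0, n)[:, None]
    models = []
    for m in range(spec.n_models):
        if spec.noise > 0:
            # low-frequency bend (common NMR-ensemble motif) + local jitter
            bend = rng.standard_normal(3)[None, :] * np.sin(math.pi * t) * spec.noise * 3.0
            jitter = rng.normal(0.0, spec.noise, (n, 3))
            coords = base.coords + bend + jitter
        else:
            coords = base.coords.copy()
        models.append(AtomicStructure.from_ca(
            coords, sequence=base.sequence(), model_id=m + 1,
        ))
    return ConformerEnsemble(entry_id=f"synthetic-{spec.seed}", models=models)


def make_noisy_profile(
    structure: AtomicStructure,
    q_grid: np.ndarray,
    relative_noise: float = 0.05,
    seed: int = 0,
) -> ScatteringProfile:
    """Experimental-style scattering profile of a structure.

    Debye intensities with multiplicative Gaussian noise of the stated
    relative amplitude; the uncertainty column is set to the matching
    absolute sigma, so a correctly specified fit to the noiseless model
    yields a chi-square near one.
    """
    if relative_noise < 0:
        raise InvalidParameterError("relative noise must be non-negative")
    clean = debye_intensity(structure, q_grid)
    if relative_noise == 0:
        sigma = np.full_like(clean.i, max(float(clean.i.max()) * 1e-6, 1e-12))
        return ScatteringProfile(q=clean.q, i=clean.i.copy(), sigma=sigma)
    rng = np.random.default_rng(seed)
    noisy = clean.i * (1.0 + rng.normal(0.0, relative_noise, clean.i.shape))
    sigma = np.maximum(relative_noise * clean.i, 1e-12)
    return ScatteringProfile(q=clean.q, i=noisy, sigma=sigma)
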