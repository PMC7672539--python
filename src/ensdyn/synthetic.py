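"""Ground-truth-annotated synthetic ensembles for pipeline validation.

The generator emulates the statistical structure the analysis pipeline
assumes, for four labelled states of one domain:

* ``ff``  free, full-length
* ``fd``  free, C-terminally truncated
* ``cf``  ligand complex, full-length
* ``cd``  ligand complex, truncated

Each conformer is  ``scaffold + a1*u1 + a2*u2 + noise``  where ``u1``/``u2``
are two planted orthonormal collective modes (rigid-body components
projected out, so superposition leaves them intact) and the amplitudes
``a1``/``a2`` are drawn from per-state two-component Gaussian mixtures.
Mode 1 models an opening-closing motion (positive side = open), mode 2 a
narrow-wide transition (positive side = narrow); per-state component
weights set the designed occupancies.

On top of the collective motion:

* every residue's amide N-H and methyl-axis vectors wobble on a cone rim of
  per-residue semi-angle theta, giving the analytic order parameter
  ``S2 = 3/2*(sin^4(theta)/2 + cos^4(theta)) - 1/2``;
* per-state isotropic noise scales are chosen so the analytic Gaussian
  (Schlitter) entropies of the designed covariances yield a prescribed
  binding-entropy ratio (the ``cd`` scale is solved numerically);
* one residue pair's side chains are displaced into contact in designated
  states (a planted discriminative contact).

Every designed quantity is recorded in a JSON-serializable ground-truth
manifest so each pipeline stage can be validated independently.  A fixed
seed gives byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from . import entropy as entropy_mod
from .ensemble_io import AtomRecord, Ensemble, write_ensemble
from .elements import element_params
from .order_parameters import BACKBONE_NH, METHYL_AXIS, OrderParameterTable

__all__ = [
    "StateSpec",
    "SyntheticSpec",
    "StudyData",
    "cone_rim_s2",
    "generate_study",
    "AlignmentFixture",
    "generate_alignment_fixture",
]

STATE_ORDER = ("ff", "fd", "cf", "cd")

_NH_BOND = 1.02  # A
_CC_BOND = 1.52  # A


def cone_rim_s2(theta_deg: float | np.ndarray) -> float | np.ndarray:
    """Analytic S2 of a unit vector uniformly distributed on a cone rim."""
    t = np.deg2rad(theta_deg)
    return 1.5 * (np.sin(t) ** 4 / 2.0 + np.cos(t) ** 4) - 0.5


@dataclass(frozen=True)
class StateSpec:
    """Per-state mixture weights and covariance scale.

    ``mode1_open_weight`` is the probability mass of the positive (open)
    component along mode 1; ``mode2_narrow_weight`` likewise for mode 2.
    ``noise_scale`` is the per-coordinate SD (A) of the isotropic noise;
    ``None`` means "solve for the designed entropy ratio" (only the ``cd``
    state may be left unsolved).
    """

    mode1_open_weight: float
    mode2_narrow_weight: float
    noise_scale: float | None

    def __post_init__(self) -> None:
        for w in (self.mode1_open_weight, self.mode2_narrow_weight):
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"mixture weight {w} outside [0, 1]")
        if self.noise_scale is not None and self.noise_scale < 0:
            raise ValueError("noise scale must be non-negative")


def _default_states() -> dict[str, StateSpec]:
    # Qualitative pattern of the analysed domain family: bound states
    # predominantly closed, the free truncated form bimodal, the free
    # full-length form almost exclusively open; full-length forms lean
    # narrow, truncated forms wide.  The free truncated state gets the
    # largest covariance scale (highest entropy); the cd scale is solved
    # for the designed binding-entropy ratio.
    return {
        "ff": StateSpec(0.95, 0.87, 0.60),
        "fd": StateSpec(0.50, 0.30, 0.75),
        "cf": StateSpec(0.10, 0.50, 0.50),
        "cd": StateSpec(0.10, 0.31, None),
    }


@dataclass
class SyntheticSpec:
    """Full description of the synthetic study (the stated world)."""

    n_residues: int = 64
    first_residue: int = 1
    n_models: int = 808
    n_replicas: int = 8
    states: dict[str, StateSpec] = field(default_factory=_default_states)
    # mixture components along each mode: (positive mean, negative mean), SD
    mode1_means: tuple[float, float] = (3.0, -3.0)
    mode1_sd: float = 0.7
    mode2_means: tuple[float, float] = (2.0, -2.0)
    mode2_sd: float = 0.6
    # cone-rim wobble semi-angles; None -> smooth default profile
    backbone_theta_deg: np.ndarray | None = None
    methyl_theta_deg: np.ndarray | None = None
    # planted contact: residue index pair (0-based; None -> auto), per-side
    # displacement (A) toward each other, states in which it is applied
    contact_pair: tuple[int, int] | None = None
    contact_displacement: float = 3.0
    contact_states: tuple[str, ...] = ("cf", "cd")
    target_entropy_ratio: float = 4.0
    temperature: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.states) != set(STATE_ORDER):
            raise ValueError(f"states must be exactly {STATE_ORDER}")
        if self.n_residues < 8:
            raise ValueError("need at least 8 residues")
        unsolved = [k for k, s in self.states.items() if s.noise_scale is None]
        if unsolved and unsolved != ["cd"]:
            raise ValueError("only the 'cd' noise scale may be solved for")
        if self.backbone_theta_deg is None:
            i = np.arange(self.n_residues)
            self.backbone_theta_deg = 12.0 + 8.0 * np.sin(2 * np.pi * i / self.n_residues) ** 2
            self.backbone_theta_deg[[0, -1]] = 45.0  # frayed termini
        if self.methyl_theta_deg is None:
            i = np.arange(self.n_residues)
            self.methyl_theta_deg = 18.0 + 14.0 * np.sin(1.0 + 2 * np.pi * i / self.n_residues) ** 2
        self.backbone_theta_deg = np.asarray(self.backbone_theta_deg, float)
        self.methyl_theta_deg = np.asarray(self.methyl_theta_deg, float)
        for name, arr in (("backbone", self.backbone_theta_deg),
                          ("methyl", self.methyl_theta_deg)):
            if arr.shape != (self.n_residues,):
                raise ValueError(f"{name} theta array must have one entry per residue")


# ---------------------------------------------------------------------------
# scaffold geometry
# ---------------------------------------------------------------------------

@dataclass
class _Scaffold:
    """Deterministic mean geometry plus local frames for the wobble cones."""

    atoms: list[AtomRecord]
    base_xyz: np.ndarray        # (3*n_res, 3): N, CA, CB per residue
    heavy_to_base: np.ndarray   # (4*n_res,): base index feeding each heavy atom
    atom_order: dict            # index arrays into the full atom list
    nh_frames: np.ndarray       # (n_res, 3, 3): rows e1, e2, axis
    methyl_frames: np.ndarray
    resnums: np.ndarray


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def _build_scaffold(spec: SyntheticSpec) -> _Scaffold:
    n = spec.n_residues
    i = np.arange(n)
    # gentle superhelical CA trace, ~3.6 A between consecutive residues
    theta = 0.55 * i
    ca = np.stack([6.0 * np.cos(theta), 6.0 * np.sin(theta), 1.5 * i], axis=1)

    tang = np.empty_like(ca)
    tang[1:-1] = ca[2:] - ca[:-2]
    tang[0] = ca[1] - ca[0]
    tang[-1] = ca[-1] - ca[-2]
    tang = _unit(tang)
    zhat = np.array([0.0, 0.0, 1.0])
    norm_v = np.cross(tang, zhat)
    bad = np.linalg.norm(norm_v, axis=1) < 1e-6
    norm_v[bad] = np.array([1.0, 0.0, 0.0])
    norm_v = _unit(norm_v)
    binorm = np.cross(tang, norm_v)

    n_pos = ca + 1.46 * _unit(-tang + 0.7 * norm_v)
    cb = ca + 1.53 * (-norm_v)

    def frames(axis: np.ndarray) -> np.ndarray:
        axis = _unit(axis)
        e1 = _unit(tang - (tang * axis).sum(1, keepdims=True) * axis)
        e2 = np.cross(axis, e1)
        return np.stack([e1, e2, axis], axis=1)

    nh_frames = frames(binorm)
    methyl_frames = frames(-norm_v + 0.4 * tang)

    base = np.empty((3 * n, 3))
    base[0::3] = n_pos
    base[1::3] = ca
    base[2::3] = cb

    resnums = spec.first_residue + i
    atoms: list[AtomRecord] = []
    serial = 1
    for r in range(n):
        for name, elem in (("N", "N"), ("H", "H"), ("CA", "C"), ("CB", "C"), ("CG", "C")):
            mass, rvdw = element_params(elem)
            atoms.append(AtomRecord(
                serial=serial, name=name, element=elem,
                residue_number=int(resnums[r]), residue_name="UNK", chain="A",
                mass=mass, vdw_radius=rvdw,
            ))
            serial += 1

    atom_order = {
        "N": np.arange(n) * 5 + 0,
        "H": np.arange(n) * 5 + 1,
        "CA": np.arange(n) * 5 + 2,
        "CB": np.arange(n) * 5 + 3,
        "CG": np.arange(n) * 5 + 4,
    }
    # heavy atom order after dropping H: N, CA, CB, CG per residue
    heavy_to_base = np.empty(4 * n, dtype=int)
    heavy_to_base[0::4] = 3 * np.arange(n)      # N
    heavy_to_base[1::4] = 3 * np.arange(n) + 1  # CA
    heavy_to_base[2::4] = 3 * np.arange(n) + 2  # CB
    heavy_to_base[3::4] = 3 * np.arange(n) + 2  # CG rides on CB
    return _Scaffold(atoms=atoms, base_xyz=base, heavy_to_base=heavy_to_base,
                     atom_order=atom_order, nh_frames=nh_frames,
                     methyl_frames=methyl_frames, resnums=resnums)


def _rigid_basis(xyz: np.ndarray) -> np.ndarray:
    """Orthonormal basis (3N, 6) of infinitesimal rigid-body fields."""
    n = xyz.shape[0]
    centered = xyz - xyz.mean(0)
    fields = []
    for k in range(3):
        t = np.zeros((n, 3))
        t[:, k] = 1.0
        fields.append(t.ravel())
    for k in range(3):
        omega = np.zeros(3)
        omega[k] = 1.0
        fields.append(np.cross(omega, centered).ravel())
    q, _ = np.linalg.qr(np.stack(fields, axis=1))
    return q


def _planted_modes(spec: SyntheticSpec, scaf: _Scaffold) -> tuple[np.ndarray, np.ndarray]:
    """Two orthonormal base-atom displacement fields with no rigid component."""
    n = spec.n_residues
    nb = 3 * n

    def block_field(lo: int, hi: int, direction: np.ndarray) -> np.ndarray:
        u = np.zeros((nb, 3))
        span = hi - lo
        for j, r in enumerate(range(lo, hi)):
            env = np.sin(np.pi * (j + 0.5) / span) ** 2
            for off in range(3):  # N, CA, CB of residue r
                u[3 * r + off] = env * direction
        return u.ravel()

    raw1 = block_field(n // 5, n // 5 + max(4, n // 6), np.array([1.0, 0.0, 0.0]))
    raw2 = block_field(3 * n // 5, 3 * n // 5 + max(4, n // 6), np.array([0.0, 1.0, 0.0]))

    q = _rigid_basis(scaf.base_xyz)
    u1 = raw1 - q @ (q.T @ raw1)
    u1 /= np.linalg.norm(u1)
    u2 = raw2 - q @ (q.T @ raw2)
    u2 -= (u1 @ u2) * u1
    u2 /= np.linalg.norm(u2)
    return u1, u2


def _mixture_variance(means: tuple[float, float], sd: float, w_pos: float) -> float:
    mu_p, mu_n = means
    mean = w_pos * mu_p + (1 - w_pos) * mu_n
    second = w_pos * (sd**2 + mu_p**2) + (1 - w_pos) * (sd**2 + mu_n**2)
    return second - mean**2


def _wobble_covariance(frame: np.ndarray, theta_deg: float, bond: float) -> np.ndarray:
    """3x3 covariance of a cone-rim vector: bond^2 sin^2(theta)/2 on the rim plane."""
    e1, e2 = frame[0], frame[1]
    s2 = np.sin(np.deg2rad(theta_deg)) ** 2
    return bond**2 * s2 / 2.0 * (np.outer(e1, e1) + np.outer(e2, e2))


def _designed_heavy_covariance(
    spec: SyntheticSpec, scaf: _Scaffold, u1: np.ndarray, u2: np.ndarray,
    state: StateSpec, noise_scale: float,
) -> entropy_mod.CovarianceModel:
    """Analytic covariance of the heavy atoms (N, CA, CB, CG) of one state."""
    v1 = _mixture_variance(spec.mode1_means, spec.mode1_sd, state.mode1_open_weight)
    v2 = _mixture_variance(spec.mode2_means, spec.mode2_sd, state.mode2_narrow_weight)
    nb = scaf.base_xyz.shape[0]
    sigma_base = (noise_scale**2) * np.eye(3 * nb)
    sigma_base += v1 * np.outer(u1, u1) + v2 * np.outer(u2, u2)

    # expand base covariance onto heavy atoms (CG inherits CB)
    idx = (3 * scaf.heavy_to_base[:, None] + np.arange(3)[None, :]).ravel()
    sigma = sigma_base[np.ix_(idx, idx)].copy()
    n = spec.n_residues
    for r in range(n):
        h_cg = 4 * r + 3
        block = _wobble_covariance(scaf.methyl_frames[r],
                                   float(spec.methyl_theta_deg[r]), _CC_BOND)
        s = slice(3 * h_cg, 3 * h_cg + 3)
        sigma[s, s] += block

    masses = np.array([element_params(e)[0] for e in ("N", "C", "C", "C")] * n)
    mean = scaf.base_xyz[scaf.heavy_to_base]
    return entropy_mod.CovarianceModel(
        matrix=sigma, masses=masses, mean=mean,
        n_models=spec.n_models, selection="heavy (designed)",
    )


def _solve_noise_scales(
    spec: SyntheticSpec, scaf: _Scaffold, u1: np.ndarray, u2: np.ndarray
) -> tuple[dict[str, float], dict[str, float]]:
    """Fix per-state noise scales; solve sigma_cd for the designed ratio.

    Returns (noise scales, analytic Schlitter entropies per state).
    """
    def analytic_s(state_key: str, sigma: float) -> float:
        c = _designed_heavy_covariance(spec, scaf, u1, u2, spec.states[state_key], sigma)
        return entropy_mod.schlitter_entropy(c, spec.temperature)

    scales = {k: s.noise_scale for k, s in spec.states.items()}
    entropies: dict[str, float] = {}
    for k in ("ff", "fd", "cf"):
        if scales[k] is None:  # pragma: no cover - guarded in SyntheticSpec
            raise ValueError(f"state {k} needs an explicit noise scale")
        entropies[k] = analytic_s(k, scales[k])
    if scales["cd"] is None:
        target = entropies["fd"] + spec.target_entropy_ratio * (
            entropies["cf"] - entropies["ff"]
        )
        f = lambda s: analytic_s("cd", s) - target
        lo, hi = 0.05, scales["fd"]
        if f(lo) * f(hi) > 0:
            raise ValueError(
                "cannot solve cd noise scale for the designed entropy ratio; "
                "adjust the ff/fd/cf scales or the target ratio"
            )
        scales["cd"] = float(brentq(f, lo, hi, rtol=1e-8))
    entropies["cd"] = analytic_s("cd", scales["cd"])
    return scales, entropies  # type: ignore[return-value]


def _population_axes(
    spec: SyntheticSpec, v1: np.ndarray, v2: np.ndarray, scales: Mapping[str, float]
) -> dict:
    """Analytic principal axes and occupancies of the pooled CA covariance.

    The per-state mixture means are correlated across states (the bound
    states lean both closed and wide), so the pooled covariance's leading
    eigenvectors are rotated within the span of the planted fields ``v1``,
    ``v2`` (the CA restrictions of the planted modes, not normalized).
    The population axes -- what a pooled PCA estimates -- and the exact
    occupancies along them are computed here in closed form; they are the
    ground truth the pipeline is validated against.
    """
    # state means of the mixture amplitudes
    m1 = {k: spec.states[k].mode1_open_weight * spec.mode1_means[0]
          + (1 - spec.states[k].mode1_open_weight) * spec.mode1_means[1]
          for k in STATE_ORDER}
    m2 = {k: spec.states[k].mode2_narrow_weight * spec.mode2_means[0]
          + (1 - spec.states[k].mode2_narrow_weight) * spec.mode2_means[1]
          for k in STATE_ORDER}
    var1 = {k: _mixture_variance(spec.mode1_means, spec.mode1_sd,
                                 spec.states[k].mode1_open_weight) for k in STATE_ORDER}
    var2 = {k: _mixture_variance(spec.mode2_means, spec.mode2_sd,
                                 spec.states[k].mode2_narrow_weight) for k in STATE_ORDER}
    m1bar = np.mean([m1[k] for k in STATE_ORDER])
    m2bar = np.mean([m2[k] for k in STATE_ORDER])
    # pooled second moments of the amplitudes about the pooled mean
    p1 = np.mean([var1[k] + (m1[k] - m1bar) ** 2 for k in STATE_ORDER])
    p2 = np.mean([var2[k] + (m2[k] - m2bar) ** 2 for k in STATE_ORDER])
    p12 = np.mean([(m1[k] - m1bar) * (m2[k] - m2bar) for k in STATE_ORDER])

    basis, _ = np.linalg.qr(np.stack([v1, v2], axis=1))
    r1, r2 = basis.T @ v1, basis.T @ v2
    a2 = (p1 * np.outer(r1, r1) + p2 * np.outer(r2, r2)
          + p12 * (np.outer(r1, r2) + np.outer(r2, r1)))
    lam, evec = np.linalg.eigh(a2)
    order = np.argsort(lam)[::-1]
    lam, evec = lam[order], evec[:, order]
    axes = [basis @ evec[:, i] for i in range(2)]

    # orient: pooled complex states get non-positive mean projection
    for i, w in enumerate(axes):
        mean_c = np.mean([
            (m1[k] - m1bar) * (w @ v1) + (m2[k] - m2bar) * (w @ v2)
            for k in ("cf", "cd")
        ])
        if mean_c > 0:
            axes[i] = -w

    comps1 = [(spec.mode1_means[0], "pos"), (spec.mode1_means[1], "neg")]
    comps2 = [(spec.mode2_means[0], "pos"), (spec.mode2_means[1], "neg")]

    def occupancy(state_key: str, w: np.ndarray) -> float:
        st = spec.states[state_key]
        ca_, cb_ = float(w @ v1), float(w @ v2)
        shift = ca_ * m1bar + cb_ * m2bar
        s = np.sqrt(ca_**2 * spec.mode1_sd**2 + cb_**2 * spec.mode2_sd**2
                    + scales[state_key] ** 2)
        p = 0.0
        for mu1, tag1 in comps1:
            w1_ = st.mode1_open_weight if tag1 == "pos" else 1 - st.mode1_open_weight
            for mu2, tag2 in comps2:
                w2_ = st.mode2_narrow_weight if tag2 == "pos" else 1 - st.mode2_narrow_weight
                arg = ca_ * mu1 + cb_ * mu2 - shift
                if s > 0:
                    p += w1_ * w2_ * norm.cdf(arg / s)
                else:  # degenerate (zero-spread) component: a point mass
                    p += w1_ * w2_ * (0.5 if arg == 0 else float(arg > 0))
        return float(p)

    return {
        "axes": axes,
        "eigenvalues_plane": lam.tolist(),
        "occupancy_open": {k: occupancy(k, axes[0]) for k in STATE_ORDER},
        "occupancy_narrow": {k: occupancy(k, axes[1]) for k in STATE_ORDER},
        "state_means": {"mode1": m1, "mode2": m2},
    }


def _default_contact_pair(spec: SyntheticSpec, scaf: _Scaffold) -> tuple[int, int]:
    """Residue pair (0-based) whose CB-CB scaffold distance is closest to 10 A."""
    cb = scaf.base_xyz[2::3]
    n = spec.n_residues
    best, best_err = (0, 3), np.inf
    for i in range(n):
        for j in range(i + 3, n):
            err = abs(np.linalg.norm(cb[i] - cb[j]) - 10.0)
            if err < best_err:
                best, best_err = (i, j), err
    return best


# ---------------------------------------------------------------------------
# study generation
# ---------------------------------------------------------------------------

@dataclass
class StudyData:
    """Output of :func:`generate_study`."""

    ensembles: dict[str, Ensemble]
    s2_table: OrderParameterTable
    manifest: dict

    def write(self, outdir: str | Path) -> None:
        """Write four multi-model PDBs, the S2 TSV and the manifest JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for key, e in self.ensembles.items():
            write_ensemble(e, outdir / f"{key}.pdb")
        self.s2_table.to_tsv(outdir / "s2_reference.tsv",
                             comment="analytic reference S2 (synthetic ground truth)")
        (outdir / "manifest.json").write_text(json.dumps(self.manifest, indent=2))


def generate_study(spec: SyntheticSpec | None = None, seed: int | None = None) -> StudyData:
    """Generate the four-state synthetic study with its ground-truth manifest."""
    spec = spec or SyntheticSpec()
    if seed is not None:
        spec.seed = seed
    rng = np.random.default_rng(spec.seed)
    scaf = _build_scaffold(spec)
    u1, u2 = _planted_modes(spec, scaf)
    scales, analytic_s = _solve_noise_scales(spec, scaf, u1, u2)

    n = spec.n_residues
    n_models = spec.n_models
    pair = spec.contact_pair or _default_contact_pair(spec, scaf)
    i0, j0 = pair
    cb = scaf.base_xyz[2::3]
    contact_dir = _unit(cb[j0] - cb[i0])
    replica_ids = (np.arange(n_models) * spec.n_replicas) // n_models

    ca_idx3 = (3 * (3 * np.arange(n) + 1)[:, None] + np.arange(3)[None, :]).ravel()
    u1_ca = u1[ca_idx3]
    u2_ca = u2[ca_idx3]
    c1 = float(np.linalg.norm(u1_ca))
    c2 = float(np.linalg.norm(u2_ca))
    axes = _population_axes(spec, u1_ca, u2_ca, scales)

    bb_theta = spec.backbone_theta_deg
    me_theta = spec.methyl_theta_deg
    sin_bb, cos_bb = np.sin(np.deg2rad(bb_theta)), np.cos(np.deg2rad(bb_theta))
    sin_me, cos_me = np.sin(np.deg2rad(me_theta)), np.cos(np.deg2rad(me_theta))

    ensembles: dict[str, Ensemble] = {}
    occupancies: dict[str, dict] = {}
    for key in STATE_ORDER:
        st = spec.states[key]
        sigma = scales[key]
        comp1 = rng.random(n_models) < st.mode1_open_weight
        a1 = np.where(comp1, spec.mode1_means[0], spec.mode1_means[1]) \
            + rng.normal(0.0, spec.mode1_sd, n_models)
        comp2 = rng.random(n_models) < st.mode2_narrow_weight
        a2 = np.where(comp2, spec.mode2_means[0], spec.mode2_means[1]) \
            + rng.normal(0.0, spec.mode2_sd, n_models)
        noise = rng.normal(0.0, sigma, (n_models, 3 * n * 3))

        base = scaf.base_xyz.ravel()[None, :] \
            + a1[:, None] * u1[None, :] + a2[:, None] * u2[None, :] + noise
        base = base.reshape(n_models, 3 * n, 3)
        if key in spec.contact_states:
            base[:, 3 * i0 + 2, :] += spec.contact_displacement * contact_dir
            base[:, 3 * j0 + 2, :] -= spec.contact_displacement * contact_dir

        coords = np.empty((n_models, 5 * n, 3))
        coords[:, scaf.atom_order["N"], :] = base[:, 0::3, :]
        coords[:, scaf.atom_order["CA"], :] = base[:, 1::3, :]
        coords[:, scaf.atom_order["CB"], :] = base[:, 2::3, :]

        phi_bb = rng.uniform(0.0, 2 * np.pi, (n_models, n))
        phi_me = rng.uniform(0.0, 2 * np.pi, (n_models, n))
        e1b, e2b, axb = scaf.nh_frames[:, 0], scaf.nh_frames[:, 1], scaf.nh_frames[:, 2]
        nh = _NH_BOND * (
            (sin_bb * np.cos(phi_bb))[..., None] * e1b
            + (sin_bb * np.sin(phi_bb))[..., None] * e2b
            + cos_bb[:, None] * axb
        )
        e1m, e2m, axm = scaf.methyl_frames[:, 0], scaf.methyl_frames[:, 1], scaf.methyl_frames[:, 2]
        cg = _CC_BOND * (
            (sin_me * np.cos(phi_me))[..., None] * e1m
            + (sin_me * np.sin(phi_me))[..., None] * e2m
            + cos_me[:, None] * axm
        )
        coords[:, scaf.atom_order["H"], :] = coords[:, scaf.atom_order["N"], :] + nh
        coords[:, scaf.atom_order["CG"], :] = coords[:, scaf.atom_order["CB"], :] + cg

        ensembles[key] = Ensemble(
            atoms=scaf.atoms, coords=coords, state_label=key,
            replica_ids=replica_ids.copy(), source=f"synthetic seed={spec.seed}",
        )
        occupancies[key] = {
            "open": axes["occupancy_open"][key],
            "narrow": axes["occupancy_narrow"][key],
            "open_weight": st.mode1_open_weight,
            "narrow_weight": st.mode2_narrow_weight,
        }

    s2_rows = []
    for r in range(n):
        s2_rows.append((int(scaf.resnums[r]), BACKBONE_NH, float(cone_rim_s2(bb_theta[r]))))
        s2_rows.append((int(scaf.resnums[r]), METHYL_AXIS, float(cone_rim_s2(me_theta[r]))))
    s2_table = OrderParameterTable.from_records(s2_rows)

    denom = analytic_s["cf"] - analytic_s["ff"]
    ratio = (analytic_s["cd"] - analytic_s["fd"]) / denom if denom != 0 else float("nan")
    manifest = {
        "seed": spec.seed,
        "n_residues": n,
        "first_residue": spec.first_residue,
        "n_models": n_models,
        "n_replicas": spec.n_replicas,
        # population principal axes of the pooled CA covariance (unit vectors):
        # what a pooled PCA estimates, rotated within the planted-mode plane
        # because the per-state mixture means are correlated across states
        "mode1_ca_unit": axes["axes"][0].tolist(),
        "mode2_ca_unit": axes["axes"][1].tolist(),
        # raw planted displacement fields, CA restriction (unit vectors)
        "planted_mode1_ca_unit": (u1_ca / c1).tolist(),
        "planted_mode2_ca_unit": (u2_ca / c2).tolist(),
        "mode1_ca_norm": c1,
        "mode2_ca_norm": c2,
        "plane_eigenvalues_A2": axes["eigenvalues_plane"],
        "mode_variances": {
            key: {
                "mode1": _mixture_variance(spec.mode1_means, spec.mode1_sd,
                                           spec.states[key].mode1_open_weight),
                "mode2": _mixture_variance(spec.mode2_means, spec.mode2_sd,
                                           spec.states[key].mode2_narrow_weight),
            } for key in STATE_ORDER
        },
        "occupancy": occupancies,
        "noise_scales": scales,
        "analytic_schlitter": analytic_s,
        "entropy_ratio": float(ratio),
        "target_entropy_ratio": spec.target_entropy_ratio,
        "temperature": spec.temperature,
        "s2_backbone": {int(scaf.resnums[r]): float(cone_rim_s2(bb_theta[r])) for r in range(n)},
        "s2_methyl": {int(scaf.resnums[r]): float(cone_rim_s2(me_theta[r])) for r in range(n)},
        "contact_pair_residues": [int(scaf.resnums[i0]), int(scaf.resnums[j0])],
        "contact_displacement": spec.contact_displacement,
        "contact_states": list(spec.contact_states),
    }
    return StudyData(ensembles=ensembles, s2_table=s2_table, manifest=manifest)


# ---------------------------------------------------------------------------
# alignment fixtures
# ---------------------------------------------------------------------------

@dataclass
class AlignmentFixture:
    """Designed alignment blocks, their merged form and matching toy structures."""

    blocks: list
    merged: object  # AlignmentBlock (import cycle avoided)
    core_columns: list[int]  # 0-based columns of the merged alignment
    structures: dict[str, Ensemble]
    pivot: str


def generate_alignment_fixture(
    n_structures: int = 3,
    core_pattern: str = "**.**..***",
    n_blocks: int = 1,
    n_models: int = 2,
    seed: int = 0,
) -> AlignmentFixture:
    """Alignment blocks with a designed core plus matching toy CA structures.

    ``core_pattern`` marks core columns with ``*`` and non-core columns with
    ``.``; every ``.`` column gets a gap in exactly one non-pivot sequence
    (round-robin), so the designed core is exactly the ``*`` columns.  With
    ``n_blocks > 1`` the non-pivot structures are split across blocks that
    all contain the (everywhere-ungapped) pivot, and the designed merged
    alignment is returned for comparison.
    """
    from .core_mapping import AlignmentBlock  # local import; no cycle at module load

    if n_structures < 2:
        raise ValueError("need at least 2 structures")
    if not set(core_pattern) <= {"*", "."}:
        raise ValueError("core_pattern may only contain '*' and '.'")
    if n_blocks > 1 and n_structures < n_blocks + 1:
        raise ValueError("need at least one non-pivot structure per block")
    rng = np.random.default_rng(seed)
    length = len(core_pattern)
    ids = [f"S{k + 1}" for k in range(n_structures)]
    pivot = ids[0]

    letters = "ACDEFGHIKLMNPQRSTVWY"
    rows = {}
    noncore = [c for c, ch in enumerate(core_pattern) if ch == "."]
    for k, sid in enumerate(ids):
        row = [letters[int(x)] for x in rng.integers(0, len(letters), length)]
        rows[sid] = row
    for idx, c in enumerate(noncore):
        victim = ids[1 + idx % (n_structures - 1)]  # never the pivot
        rows[victim][c] = "-"

    tracks = {}
    structures: dict[str, Ensemble] = {}
    for k, sid in enumerate(ids):
        n_res = sum(1 for ch in rows[sid] if ch != "-")
        offset = 100 * (k + 1)
        tracks[sid] = [("A", offset + r + 1) for r in range(n_res)]
        atoms = []
        for r in range(n_res):
            mass, rvdw = element_params("C")
            atoms.append(AtomRecord(
                serial=r + 1, name="CA", element="C",
                residue_number=offset + r + 1, residue_name="UNK", chain="A",
                mass=mass, vdw_radius=rvdw,
            ))
        base = np.stack([3.8 * np.arange(n_res),
                         2.0 * np.sin(0.6 * np.arange(n_res) + k),
                         2.0 * np.cos(0.4 * np.arange(n_res))], axis=1)
        coords = base[None] + rng.normal(0.0, 0.3, (n_models, n_res, 3))
        structures[sid] = Ensemble(atoms=atoms, coords=coords,
                                   state_label=sid, source="synthetic alignment fixture")

    merged = AlignmentBlock(
        sequences={sid: "".join(rows[sid]) for sid in ids},
        tracks={sid: list(tracks[sid]) for sid in ids},
    )
    if n_blocks == 1:
        blocks = [merged]
    else:
        others = ids[1:]
        chunks = np.array_split(np.array(others, dtype=object), n_blocks)
        blocks = []
        for chunk in chunks:
            members = [pivot] + [str(s) for s in chunk]
            blocks.append(AlignmentBlock(
                sequences={sid: "".join(rows[sid]) for sid in members},
                tracks={sid: list(tracks[sid]) for sid in members},
            ))
    core_columns = [c for c, ch in enumerate(core_pattern) if ch == "*"]
    return AlignmentFixture(blocks=blocks, merged=merged, core_columns=core_columns,
                            structures=structures, pivot=pivot)
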