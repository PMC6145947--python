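"""Parametric radial-frequency 3D shape space.

Shapes are spheres whose radius is modulated by six sinusoidal components.
Each component has four parameters — frequency (cycles per revolution),
amplitude (fraction of the base radius), phase (rad) and orientation (rad,
tilt of the component's modulation axis away from the z-axis) — giving a
24-dimensional shape space.  Two fixed prototype shapes span a morph
continuum; adaptor clouds and probe pairs are constructed at controlled
Euclidean distances in this space.

Distances are measured on a scaled 24-vector so that no parameter family
(frequency, amplitude, phase, orientation) dominates; see
:data:`PARAM_SCALES`.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "SinusoidComponent",
    "ShapeParams",
    "MorphContinuum",
    "AdaptorSet",
    "ProbePair",
    "TriMesh",
    "PARAM_SCALES",
    "N_COMPONENTS",
    "N_PARAMS",
    "default_prototypes",
    "radius_function",
    "render_mesh",
    "shape_distance",
    "morph_continuum",
    "jitter_adaptors",
    "probe_pair",
    "write_obj",
    "shapes_to_csv",
    "shapes_to_json",
]

N_COMPONENTS = 6
N_PARAMS = 4 * N_COMPONENTS  # 24 free parameters

#: Per-family scale constants dividing (frequency, amplitude, phase,
#: orientation) before Euclidean distances are taken.  Chosen so that a
#: "typical" excursion in each family contributes comparably.
PARAM_SCALES = np.tile(np.array([1.0, 0.05, np.pi / 4, np.pi / 4]), N_COMPONENTS)

# vector layout: component-major, (frequency, amplitude, phase, orientation)
_FREQ_IDX = np.arange(0, N_PARAMS, 4)
_AMP_IDX = np.arange(1, N_PARAMS, 4)
_PHASE_IDX = np.arange(2, N_PARAMS, 4)
_ORIENT_IDX = np.arange(3, N_PARAMS, 4)

#: indices of the 12 amplitude/orientation coordinates jittered for adaptors
JITTER_IDX = np.sort(np.concatenate([_AMP_IDX, _ORIENT_IDX]))


@dataclass(frozen=True)
class SinusoidComponent:
    """One sinusoidal radius modulation."""

    frequency: float
    amplitude: float
    phase: float
    orientation: float


@dataclass(frozen=True)
class ShapeParams:
    """A point in the 24-dimensional shape space.

    Parameters
    ----------
    components
        Exactly six :class:`SinusoidComponent` records.
    strict
        When True (used for prototypes) frequencies must be integers; shapes
        derived by morphing or random displacement may carry fractional
        frequencies and are validated with ``strict=False``.
    """

    components: tuple[SinusoidComponent, ...]
    strict: bool = field(default=False, compare=False)

    def __post_init__(self):
        if len(self.components) != N_COMPONENTS:
            raise ValueError(
                f"expected {N_COMPONENTS} sinusoidal components, got {len(self.components)}"
            )
        amps = [c.amplitude for c in self.components]
        if min(amps) < 0:
            raise ValueError("amplitudes must be non-negative")
        if sum(amps) >= 1.0:
            raise ValueError(
                f"amplitude sum {sum(amps):.3f} >= 1.0: modulated radius not strictly positive"
            )
        for c in self.components:
            if c.frequency < 2:
                raise ValueError("frequencies must be >= 2 for a closed surface")
            if self.strict and abs(c.frequency - round(c.frequency)) > 1e-12:
                raise ValueError("prototype frequencies must be integers")

    @property
    def n_free_parameters(self) -> int:
        return N_PARAMS

    def to_vector(self) -> np.ndarray:
        """Canonical 24-vector: component-major (f, A, phi, o)."""
        v = np.empty(N_PARAMS)
        for i, c in enumerate(self.components):
            v[4 * i : 4 * i + 4] = (c.frequency, c.amplitude, c.phase, c.orientation)
        return v

    @classmethod
    def from_vector(cls, v: Sequence[float], strict: bool = False) -> "ShapeParams":
        v = np.asarray(v, dtype=float)
        if v.shape != (N_PARAMS,):
            raise ValueError(f"expected a {N_PARAMS}-vector, got shape {v.shape}")
        comps = tuple(
            SinusoidComponent(v[4 * i], v[4 * i + 1], v[4 * i + 2], v[4 * i + 3])
            for i in range(N_COMPONENTS)
        )
        return cls(comps, strict=strict)


@dataclass(frozen=True)
class MorphContinuum:
    """Linear interpolation between two prototypes (81 levels for 80 steps)."""

    prototype_a: ShapeParams
    prototype_b: ShapeParams
    levels: tuple[ShapeParams, ...]

    @property
    def n_steps(self) -> int:
        return len(self.levels) - 1


@dataclass(frozen=True)
class AdaptorSet:
    """A cloud of adaptor shapes at a fixed distance from a prototype."""

    prototype: ShapeParams
    adaptors: tuple[ShapeParams, ...]
    radius: float
    seed: int


@dataclass(frozen=True)
class ProbePair:
    """Two probes symmetric about a prototype along a random direction."""

    prototype: ShapeParams
    direction: np.ndarray  # unit vector in the *scaled* 24-space
    offset: float
    probes: tuple[ShapeParams, ShapeParams]


@dataclass(frozen=True)
class TriMesh:
    vertices: np.ndarray  # (V, 3) float
    faces: np.ndarray  # (F, 3) int, CCW outward

    def euler_characteristic(self) -> int:
        v = len(self.vertices)
        f = len(self.faces)
        edges = set()
        for a, b, c in self.faces:
            for e in ((a, b), (b, c), (c, a)):
                edges.add(tuple(sorted(e)))
        return v - len(edges) + f


# ---------------------------------------------------------------------------
# geometry


def _component_frame(orientation: float) -> tuple[np.ndarray, np.ndarray]:
    """In-plane basis of the component frame: z-axis rotated by ``orientation``
    within the xz-plane.  Returns (e1, e2); azimuth = atan2(d.e2, d.e1)."""
    co, so = math.cos(orientation), math.sin(orientation)
    e1 = np.array([co, 0.0, -so])
    e2 = np.array([0.0, 1.0, 0.0])
    return e1, e2


def radius_function(params: ShapeParams, direction: np.ndarray) -> float | np.ndarray:
    """Modulated radius along ``direction``.

    r(d) = 1 + sum_i A_i * sin(f_i * psi_i(d) + phi_i), where psi_i is the
    azimuth of d about the component's tilted axis.  ``direction`` may be a
    single unit 3-vector or an (N, 3) array of unit vectors.
    """
    d = np.asarray(direction, dtype=float)
    single = d.ndim == 1
    d = np.atleast_2d(d)
    r = np.ones(len(d))
    for c in params.components:
        e1, e2 = _component_frame(c.orientation)
        psi = np.arctan2(d @ e2, d @ e1)
        r += c.amplitude * np.sin(c.frequency * psi + c.phase)
    if np.any(r <= 0):  # excluded by the amplitude-sum invariant
        raise AssertionError("non-positive radius despite amplitude invariant")
    return float(r[0]) if single else r


def render_mesh(params: ShapeParams, n_lat: int = 32, n_lon: int = 32) -> TriMesh:
    """Triangulate the shape on a latitude–longitude grid with pole fans.

    Deterministic: identical parameters and resolution yield byte-identical
    vertex and face arrays.
    """
    if n_lat < 8 or n_lon < 8:
        raise ValueError("degenerate mesh: require n_lat >= 8 and n_lon >= 8")
    thetas = np.pi * np.arange(1, n_lat) / n_lat  # interior rings
    phis = 2 * np.pi * np.arange(n_lon) / n_lon
    dirs = [np.array([0.0, 0.0, 1.0])]
    for th in thetas:
        st, ct = math.sin(th), math.cos(th)
        for ph in phis:
            dirs.append(np.array([st * math.cos(ph), st * math.sin(ph), ct]))
    dirs.append(np.array([0.0, 0.0, -1.0]))
    dirs = np.asarray(dirs)
    radii = radius_function(params, dirs)
    vertices = dirs * radii[:, None]

    def ring(i: int, k: int) -> int:  # ring i in 0..n_lat-2, longitude k
        return 1 + i * n_lon + (k % n_lon)

    faces = []
    south = len(vertices) - 1
    for k in range(n_lon):  # north fan
        faces.append((0, ring(0, k), ring(0, k + 1)))
    for i in range(n_lat - 2):  # quad strips
        for k in range(n_lon):
            a, b = ring(i, k), ring(i, k + 1)
            c, d = ring(i + 1, k), ring(i + 1, k + 1)
            faces.append((a, c, d))
            faces.append((a, d, b))
    for k in range(n_lon):  # south fan
        faces.append((south, ring(n_lat - 2, k + 1), ring(n_lat - 2, k)))
    return TriMesh(vertices=vertices, faces=np.asarray(faces, dtype=np.int64))


# ---------------------------------------------------------------------------
# metric and constructions


def _scaled(p: ShapeParams) -> np.ndarray:
    return p.to_vector() / PARAM_SCALES


def shape_distance(p: ShapeParams, q: ShapeParams) -> float:
    """Euclidean distance between the scaled 24-vectors of two shapes."""
    return float(np.linalg.norm(_scaled(p) - _scaled(q)))


def morph_continuum(a: ShapeParams, b: ShapeParams, n_steps: int = 80) -> MorphContinuum:
    """Equal-interval morph from ``a`` (level 0) to ``b`` (level ``n_steps``).

    Interpolation is linear on the raw 24-vector (phases included — prototypes
    are chosen with phases in a common half-turn so this is unambiguous).
    """
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    va, vb = a.to_vector(), b.to_vector()
    if np.array_equal(va, vb):
        raise ValueError("prototypes must differ")
    levels = []
    for k in range(n_steps + 1):
        if k == 0:
            levels.append(a)
        elif k == n_steps:
            levels.append(b)
        else:
            levels.append(ShapeParams.from_vector(va + (k / n_steps) * (vb - va)))
    return MorphContinuum(prototype_a=a, prototype_b=b, levels=tuple(levels))


def jitter_adaptors(
    prototype: ShapeParams,
    n: int = 50,
    radius: float = 1.0,
    seed: int = 0,
    other_prototype: ShapeParams | None = None,
) -> AdaptorSet:
    """Generate ``n`` adaptors at exact distance ``radius`` from the prototype.

    Zero-mean Gaussian perturbations are drawn on the 12 amplitude and
    orientation coordinates (scaled space), rescaled to exact length
    ``radius``, and applied; frequency and phase coordinates are untouched.
    When ``other_prototype`` is given, ``radius`` must be smaller than half
    the inter-prototype distance so the adaptor cloud stays within its class.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if other_prototype is not None:
        half = shape_distance(prototype, other_prototype) / 2
        if radius >= half:
            raise ValueError(
                f"adaptor cloud overlaps other class: radius {radius:.4g} >= "
                f"half inter-prototype distance {half:.4g}"
            )
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF]))
    base = _scaled(prototype)
    adaptors = []
    attempts = 0
    while len(adaptors) < n:
        attempts += 1
        if attempts > 100 * n:
            raise ValueError("radius too large for the amplitude-sum invariant")
        g = rng.standard_normal(len(JITTER_IDX))
        pert = radius * g / np.linalg.norm(g)
        cand = prototype.to_vector()  # frozen coordinates stay bit-identical
        cand[JITTER_IDX] = (base[JITTER_IDX] + pert) * PARAM_SCALES[JITTER_IDX]
        if np.any(cand[_AMP_IDX] < 0) or cand[_AMP_IDX].sum() >= 1.0:
            continue
        adaptors.append(ShapeParams.from_vector(cand))
    return AdaptorSet(prototype=prototype, adaptors=tuple(adaptors), radius=radius, seed=seed)


def probe_pair(prototype: ShapeParams, offset: float, seed: int = 0) -> ProbePair:
    """Two probes at distance ``offset`` from the prototype, symmetric along a
    direction drawn uniformly on the unit sphere of the (scaled) 24-space."""
    if offset <= 0:
        raise ValueError("offset must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF]))
    base = _scaled(prototype)
    for _ in range(1000):
        g = rng.standard_normal(N_PARAMS)
        direction = g / np.linalg.norm(g)
        v1 = (base + offset * direction) * PARAM_SCALES
        v2 = (base - offset * direction) * PARAM_SCALES
        ok = True
        for v in (v1, v2):
            if np.any(v[_AMP_IDX] < 0) or v[_AMP_IDX].sum() >= 1.0 or np.any(v[_FREQ_IDX] < 2):
                ok = False
                break
        if ok:
            p1 = ShapeParams.from_vector(v1)
            p2 = ShapeParams.from_vector(v2)
            return ProbePair(prototype=prototype, direction=direction, offset=offset, probes=(p1, p2))
    raise ValueError("offset violates shape invariants for every sampled direction")


# ---------------------------------------------------------------------------
# fixed default prototypes (shared by all simulated subjects)

_PROTO_A = (
    # (frequency, amplitude, phase, orientation) x 6
    (3, 0.12, 0.40, 0.30),
    (4, 0.10, 1.00, 0.70),
    (5, 0.08, 1.60, 1.10),
    (6, 0.06, 0.70, 1.50),
    (7, 0.05, 1.20, 0.90),
    (8, 0.04, 0.30, 0.40),
)
_PROTO_B = (
    (3, 0.05, 1.20, 1.20),
    (4, 0.07, 0.50, 0.40),
    (5, 0.11, 0.90, 0.80),
    (6, 0.09, 1.50, 0.20),
    (7, 0.04, 0.80, 1.40),
    (8, 0.10, 1.10, 0.70),
)


def default_prototypes() -> tuple[ShapeParams, ShapeParams]:
    """The two fixed prototype shapes A and B.

    Both use the same integer frequency ladder (3..8 cycles/revolution) and
    differ in amplitudes, phases and orientations, so morphs between them
    retain integer frequencies.  All phases lie within a common half-turn.
    """
    a = ShapeParams(tuple(SinusoidComponent(*c) for c in _PROTO_A), strict=True)
    b = ShapeParams(tuple(SinusoidComponent(*c) for c in _PROTO_B), strict=True)
    return a, b


# ---------------------------------------------------------------------------
# serialization

_CSV_COLUMNS = [
    f"{name}{i + 1}"
    for i in range(N_COMPONENTS)
    for name in ("freq", "amp", "phase", "orient")
]


def write_obj(mesh: TriMesh, path: str | Path) -> None:
    """ASCII Wavefront OBJ (v/f records, 1-based face indices)."""
    with open(path, "w") as fh:
        for v in mesh.vertices:
            fh.write(f"v {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        for f in mesh.faces:
            fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")


def shapes_to_csv(shapes: dict[str, ShapeParams], path: str | Path) -> None:
    """One row per shape: id + 24 named parameter columns."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id"] + _CSV_COLUMNS)
        for sid, shape in shapes.items():
            w.writerow([sid] + [f"{x:.12g}" for x in shape.to_vector()])


def shapes_to_json(shapes: dict[str, ShapeParams], path: str | Path) -> None:
    payload = {sid: list(map(float, s.to_vector())) for sid, s in shapes.items()}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
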