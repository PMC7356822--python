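"""Digital phantoms and simulated acquisitions.

Everything the validation study needs as input is generated here, so the
whole pipeline runs without any scanner data:

* cylindrical CuSO4 tube phantoms in a saline tank, with relaxation
  times set by a fast-exchange relaxivity law calibrated against the
  packaged reference table;
* a schematic brain-like phantom (nested ellipsoids for WM/GM/CSF,
  paired thalami, one spherical stroke lesion);
* magnitude acquisition series (inversion-recovery TI series, multi-echo
  TE series, weighted contrasts) with Rician noise;
* the multiplicative bias model that emulates how synthetic-scan
  relaxometry deviates from conventional spin-echo references at long
  relaxation times.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from synthmri.relaxometry import AcquisitionSeries
from synthmri.signal_models import (
    BACKGROUND_LABEL,
    SequenceParams,
    TissueParams,
    synthesize_weighted,
)

__all__ = [
    "QuantitativeMaps",
    "TubeSpec",
    "PhantomSpec",
    "RelaxivityModel",
    "BrainPhantomSpec",
    "relaxation_from_concentration",
    "calibrate_relaxivity",
    "build_cylinder_phantom",
    "build_brain_phantom",
    "simulate_acquisition",
    "add_rician_noise",
    "synthetic_scan_bias",
    "bias_factors_from_table",
    "load_phantom_reference_table",
    "ir_protocol",
    "me_protocol",
    "TI_SERIES_MS",
    "TE_SERIES_MS",
    "SALINE_LABEL",
    "BRAIN_LABELS",
    "DEFAULT_BRAIN_TISSUES",
]

# Reference quantification protocols: a 16-point inversion-recovery TI
# series and a 20-echo TE series, both at TR = 10 s.
TI_SERIES_MS = (
    100.0, 300.0, 500.0, 700.0, 800.0, 900.0, 1000.0, 1100.0,
    1200.0, 1300.0, 1400.0, 1500.0, 1800.0, 2400.0, 3000.0, 4000.0,
)
TE_SERIES_MS = (
    9.9, 19.9, 29.8, 39.7, 49.6, 59.6, 69.5, 79.4, 89.4, 99.3,
    109.2, 119.2, 129.0, 139.0, 149.0, 158.8, 168.7, 178.6, 188.5, 198.4,
)
IR_REFERENCE_TR_MS = 10_000.0
IR_REFERENCE_TE_MS = 8.9

SALINE_LABEL = 1
FIRST_TUBE_LABEL = 2

BRAIN_LABELS = {"WM": 1, "GM": 2, "CSF": 3, "thalamus": 4, "lesion": 5}

# Nominal 3T tissue parameters (PD in a.u. relative to CSF = 1).  CSF T1
# sits near the null point of the FLAIR inversion time so that fluid is
# suppressed, as on a scanner.  The chronic stroke lesion is gliotic /
# fluid-rich: long T1 and T2 relative to the white matter that hosts it.
DEFAULT_BRAIN_TISSUES = {
    "WM": TissueParams(pd=0.70, t1=830.0, t2=80.0, name="WM"),
    "GM": TissueParams(pd=0.85, t1=1330.0, t2=110.0, name="GM"),
    "CSF": TissueParams(pd=1.00, t1=4300.0, t2=2000.0, name="CSF"),
    "thalamus": TissueParams(pd=0.82, t1=1100.0, t2=90.0, name="thalamus"),
    "lesion": TissueParams(pd=0.90, t1=1700.0, t2=160.0, name="lesion"),
}


def load_phantom_reference_table() -> pd.DataFrame:
    """Packaged per-concentration reference/synthetic relaxation table.

    Columns: ``quantity`` (T1|T2), ``concentration_mM``, ``reference``
    (conventional spin-echo value, ms) and 14 synthetic-scan sessions
    ``syn_1_1`` ... ``syn_2_7`` (2 days x 7 repetitions, ms).
    """
    with resources.files("synthmri.data").joinpath(
        "phantom_reference_table.csv"
    ).open() as fh:
        return pd.read_csv(fh)


SYNTHETIC_COLUMNS = tuple(f"syn_{d}_{s}" for d in (1, 2) for s in range(1, 8))


@dataclass
class QuantitativeMaps:
    """Co-registered quantitative volumes on one voxel grid.

    ``pd`` is proton density (a.u.), ``t1``/``t2`` relaxation times (ms),
    ``labels`` an integer region map (0 = background).  ``affine`` maps
    0-based voxel indices to RAS+ world mm.
    """

    pd: np.ndarray
    t1: np.ndarray
    t2: np.ndarray
    labels: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    label_names: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {np.shape(self.pd), np.shape(self.t1), np.shape(self.t2), np.shape(self.labels)}
        if len(shapes) != 1:
            raise ValueError(f"maps must share one grid, got shapes {sorted(shapes)}")
        self.labels = np.asarray(self.labels, dtype=np.int32)

    @property
    def shape(self) -> tuple:
        return np.shape(self.labels)

    def region_mask(self, label: int) -> np.ndarray:
        return self.labels == label


@dataclass(frozen=True)
class TubeSpec:
    """One sealed CuSO4 tube: concentration and cylinder geometry.

    ``center_mm`` is the in-plane (x, y) offset of the tube axis from the
    tank center, in mm.  Defaults follow the physical tubes: 7.1 cm^2
    cross-section, 6.0 cm height.
    """

    concentration: float
    center_mm: tuple = (0.0, 0.0)
    cross_section_area_cm2: float = 7.1
    height_cm: float = 6.0

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise ValueError(f"concentration must be > 0 mM, got {self.concentration}")
        if self.cross_section_area_cm2 <= 0 or self.height_cm <= 0:
            raise ValueError("tube geometry must be positive")

    @property
    def radius_mm(self) -> float:
        return 10.0 * math.sqrt(self.cross_section_area_cm2 / math.pi)

    @property
    def height_mm(self) -> float:
        return 10.0 * self.height_cm


@dataclass(frozen=True)
class PhantomSpec:
    """Saline tank with CuSO4 tubes on a regular voxel grid.

    The default grid is 128 x 128 in-plane over a 160 mm field of view
    with 20 slices at 6 mm spacing (5 mm thickness + 1 mm gap).
    """

    tubes: tuple
    tank_fill: str = "saline"
    shape: tuple = (128, 128, 20)
    field_of_view_mm: float = 160.0
    slice_spacing_mm: float = 6.0
    tank_radius_mm: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "tubes", tuple(self.tubes))
        if len(self.shape) != 3 or any(s <= 0 for s in self.shape):
            raise ValueError(f"shape must be a positive 3-tuple, got {self.shape}")

    @property
    def in_plane_voxel_mm(self) -> float:
        return self.field_of_view_mm / self.shape[0]

    @property
    def effective_tank_radius_mm(self) -> float:
        return self.tank_radius_mm if self.tank_radius_mm is not None else 0.47 * self.field_of_view_mm


@dataclass(frozen=True)
class RelaxivityModel:
    """Fast-exchange relaxivity law for a paramagnetic solute.

    1/T(C) = 1/T_solvent + r * C with r in s^-1 mM^-1, T in ms and C in
    mM.  ``r2 >= r1`` for CuSO4-like agents.
    """

    r1: float
    r2: float
    t1_solvent_ms: float
    t2_solvent_ms: float

    def __post_init__(self) -> None:
        for name in ("r1", "r2", "t1_solvent_ms", "t2_solvent_ms"):
            if getattr(self, name) <= 0 or not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be positive and finite")
        if self.r2 < self.r1:
            raise ValueError(f"r2 ({self.r2}) must be >= r1 ({self.r1})")


def relaxation_from_concentration(c, model: RelaxivityModel):
    """(T1, T2) in ms for CuSO4 concentration ``c`` in mM; broadcasts."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0) or not np.all(np.isfinite(c)):
        raise ValueError(f"concentration must be >= 0 mM, got {c!r}")
    # rates in ms^-1; r converts from s^-1 mM^-1
    t1 = 1.0 / (1.0 / model.t1_solvent_ms + model.r1 * c / 1000.0)
    t2 = 1.0 / (1.0 / model.t2_solvent_ms + model.r2 * c / 1000.0)
    if t1.ndim == 0:
        return float(t1), float(t2)
    return t1, t2


def _rate_line(conc: np.ndarray, t_ms: np.ndarray) -> tuple:
    """OLS of relaxation rate (s^-1) on concentration (mM)."""
    if np.ptp(conc) == 0:
        raise ValueError("all concentrations equal: relaxivity fit is singular")
    rate = 1000.0 / t_ms
    slope, intercept = np.polyfit(conc, rate, 1)
    return float(slope), float(intercept)


def calibrate_relaxivity(reference_table: pd.DataFrame) -> RelaxivityModel:
    """Fit r1/r2 and solvent times from a reference relaxation table.

    ``reference_table`` needs columns ``quantity`` (T1|T2),
    ``concentration_mM`` and ``reference`` (ms); each quantity needs at
    least two distinct concentrations.  The relaxivity is the slope of
    the ordinary least-squares line of 1/T versus C; the intercept gives
    the solvent relaxation rate.
    """
    models = {}
    for quantity in ("T1", "T2"):
        rows = reference_table[reference_table["quantity"] == quantity]
        if len(rows) < 2:
            raise ValueError(f"need >= 2 {quantity} rows to calibrate, got {len(rows)}")
        slope, intercept = _rate_line(
            rows["concentration_mM"].to_numpy(float), rows["reference"].to_numpy(float)
        )
        if slope <= 0 or intercept <= 0:
            raise ValueError(
                f"{quantity} calibration gave non-physical relaxivity "
                f"(slope {slope:.4g}, intercept {intercept:.4g})"
            )
        models[quantity] = (slope, 1000.0 / intercept)
    return RelaxivityModel(
        r1=models["T1"][0],
        r2=models["T2"][0],
        t1_solvent_ms=models["T1"][1],
        t2_solvent_ms=models["T2"][1],
    )


def default_relaxivity_model() -> RelaxivityModel:
    """Relaxivity model calibrated on the packaged reference table."""
    return calibrate_relaxivity(load_phantom_reference_table())


def default_tube_ring(concentrations, ring_radius_mm: float = 50.0) -> tuple:
    """Place one tube per concentration evenly on a ring around the tank."""
    concentrations = list(concentrations)
    tubes = []
    for i, c in enumerate(concentrations):
        angle = 2.0 * math.pi * i / max(len(concentrations), 1)
        tubes.append(
            TubeSpec(
                concentration=float(c),
                center_mm=(ring_radius_mm * math.cos(angle), ring_radius_mm * math.sin(angle)),
            )
        )
    return tuple(tubes)


def _grid_coordinates_mm(shape, in_plane_mm, slice_mm):
    """World mm coordinates of voxel centers, grid-centered."""
    nx, ny, nz = shape
    x = (np.arange(nx) - (nx - 1) / 2.0) * in_plane_mm
    y = (np.arange(ny) - (ny - 1) / 2.0) * in_plane_mm
    z = (np.arange(nz) - (nz - 1) / 2.0) * slice_mm
    return np.meshgrid(x, y, z, indexing="ij")


def _centered_affine(shape, in_plane_mm, slice_mm) -> np.ndarray:
    affine = np.diag([in_plane_mm, in_plane_mm, slice_mm, 1.0])
    affine[:3, 3] = [
        -(shape[0] - 1) / 2.0 * in_plane_mm,
        -(shape[1] - 1) / 2.0 * in_plane_mm,
        -(shape[2] - 1) / 2.0 * slice_mm,
    ]
    return affine


def build_cylinder_phantom(spec: PhantomSpec, model: RelaxivityModel) -> QuantitativeMaps:
    """Voxelize a saline tank with CuSO4 tubes into quantitative maps.

    Each tube gets its own integer label (2, 3, ...) with T1/T2 from
    :func:`relaxation_from_concentration`; saline is label 1, air 0.
    PD is 1 in all liquid.  Raises if tubes overlap or poke outside the
    tank.
    """
    dx = spec.in_plane_voxel_mm
    xs, ys, zs = _grid_coordinates_mm(spec.shape, dx, spec.slice_spacing_mm)
    tank_r = spec.effective_tank_radius_mm

    for i, a in enumerate(spec.tubes):
        ax, ay = a.center_mm
        if math.hypot(ax, ay) + a.radius_mm > tank_r:
            raise ValueError(f"tube {i} (c={a.concentration} mM) does not fit inside the tank")
        for b in spec.tubes[i + 1 :]:
            bx, by = b.center_mm
            if math.hypot(ax - bx, ay - by) < a.radius_mm + b.radius_mm:
                raise ValueError(
                    f"tubes at {a.center_mm} and {b.center_mm} overlap"
                )

    labels = np.zeros(spec.shape, dtype=np.int32)
    in_tank = xs**2 + ys**2 <= tank_r**2
    labels[in_tank] = SALINE_LABEL

    solvent_t1, solvent_t2 = relaxation_from_concentration(0.0, model)
    t1 = np.zeros(spec.shape)
    t2 = np.zeros(spec.shape)
    t1[in_tank] = solvent_t1
    t2[in_tank] = solvent_t2

    label_names = {BACKGROUND_LABEL: "background", SALINE_LABEL: spec.tank_fill}
    for i, tube in enumerate(spec.tubes):
        label = FIRST_TUBE_LABEL + i
        cx, cy = tube.center_mm
        in_tube = ((xs - cx) ** 2 + (ys - cy) ** 2 <= tube.radius_mm**2) & (
            np.abs(zs) <= tube.height_mm / 2.0
        )
        tube_t1, tube_t2 = relaxation_from_concentration(tube.concentration, model)
        labels[in_tube] = label
        t1[in_tube] = tube_t1
        t2[in_tube] = tube_t2
        label_names[label] = f"tube_{tube.concentration:g}mM"

    pd_map = (labels != BACKGROUND_LABEL).astype(float)
    return QuantitativeMaps(
        pd=pd_map,
        t1=t1,
        t2=t2,
        labels=labels,
        affine=_centered_affine(spec.shape, dx, spec.slice_spacing_mm),
        label_names=label_names,
    )


@dataclass(frozen=True)
class BrainPhantomSpec:
    """Schematic brain phantom: nested ellipsoids plus a lesion sphere.

    ``tissues`` maps the five region names (WM, GM, CSF, thalamus,
    lesion) to :class:`TissueParams`.  ``lesion_center_mm`` and
    ``lesion_radius_mm`` place the spherical stroke lesion inside the
    white matter; set ``lesion_radius_mm`` to 0 for a lesion-free brain.
    ``noise_sigma`` and ``seed`` are the defaults used when simulating
    acquisitions from this phantom.
    """

    tissues: dict = field(default_factory=lambda: dict(DEFAULT_BRAIN_TISSUES))
    lesion_center_mm: tuple = (30.0, 12.0, 0.0)
    lesion_radius_mm: float = 10.0
    noise_sigma: float = 0.02
    seed: int = 0
    shape: tuple = (128, 128, 20)
    field_of_view_mm: float = 192.0
    slice_spacing_mm: float = 6.0

    def __post_init__(self) -> None:
        required = set(BRAIN_LABELS) if self.lesion_radius_mm > 0 else set(BRAIN_LABELS) - {"lesion"}
        missing = required - set(self.tissues)
        if missing:
            raise ValueError(f"missing tissue parameters for {sorted(missing)}")
        if self.lesion_radius_mm > 0 and self.tissues["lesion"].t2 < self.tissues["WM"].t2:
            warnings.warn(
                "stroke lesion T2 below WM T2; expected lesion T2 > WM T2",
                stacklevel=2,
            )

    @property
    def in_plane_voxel_mm(self) -> float:
        return self.field_of_view_mm / self.shape[0]


def _ellipsoid(xs, ys, zs, center, semiaxes):
    cx, cy, cz = center
    ax, ay, az = semiaxes
    return ((xs - cx) / ax) ** 2 + ((ys - cy) / ay) ** 2 + ((zs - cz) / az) ** 2 <= 1.0


def build_brain_phantom(spec: BrainPhantomSpec) -> QuantitativeMaps:
    """Build the brain-like label map and piecewise-constant maps.

    Geometry (mm, grid-centered): a CSF ellipsoid encloses a GM
    ellipsoid which encloses the WM core; two ellipsoidal lateral
    ventricles (CSF) sit anterior of two ellipsoidal thalami; one
    spherical lesion lies in the WM.  All five region labels are
    guaranteed non-empty on the default grid.
    """
    xs, ys, zs = _grid_coordinates_mm(spec.shape, spec.in_plane_voxel_mm, spec.slice_spacing_mm)

    labels = np.zeros(spec.shape, dtype=np.int32)
    labels[_ellipsoid(xs, ys, zs, (0, 0, 0), (82.0, 74.0, 56.0))] = BRAIN_LABELS["CSF"]
    labels[_ellipsoid(xs, ys, zs, (0, 0, 0), (74.0, 66.0, 50.0))] = BRAIN_LABELS["GM"]
    labels[_ellipsoid(xs, ys, zs, (0, 0, 0), (58.0, 50.0, 40.0))] = BRAIN_LABELS["WM"]
    for side in (-1.0, 1.0):
        labels[_ellipsoid(xs, ys, zs, (side * 12.0, -20.0, 0.0), (8.0, 18.0, 10.0))] = BRAIN_LABELS["CSF"]
        labels[_ellipsoid(xs, ys, zs, (side * 12.0, 10.0, 0.0), (8.0, 11.0, 9.0))] = BRAIN_LABELS["thalamus"]

    if spec.lesion_radius_mm > 0:
        lesion = _ellipsoid(
            xs, ys, zs, spec.lesion_center_mm, (spec.lesion_radius_mm,) * 3
        )
        host = BRAIN_LABELS["WM"]
        if lesion.sum() >= (labels == host).sum():
            raise ValueError("lesion is larger than its host WM region")
        if not np.all(labels[lesion] == host):
            raise ValueError("lesion must lie entirely within white matter")
        labels[lesion] = BRAIN_LABELS["lesion"]

    pd_map = np.zeros(spec.shape)
    t1 = np.zeros(spec.shape)
    t2 = np.zeros(spec.shape)
    for name, label in BRAIN_LABELS.items():
        mask = labels == label
        if not mask.any():
            if name == "lesion" and spec.lesion_radius_mm == 0:
                continue
            raise ValueError(f"region {name} is empty on this grid")
        tissue = spec.tissues[name]
        pd_map[mask] = tissue.pd
        t1[mask] = tissue.t1
        t2[mask] = tissue.t2

    label_names = {BACKGROUND_LABEL: "background"}
    label_names.update({v: k for k, v in BRAIN_LABELS.items()})
    return QuantitativeMaps(
        pd=pd_map,
        t1=t1,
        t2=t2,
        labels=labels,
        affine=_centered_affine(spec.shape, spec.in_plane_voxel_mm, spec.slice_spacing_mm),
        label_names=label_names,
    )


def add_rician_noise(image, sigma: float, seed=None) -> np.ndarray:
    """Corrupt a noiseless magnitude image with Rician noise.

    Magnitude MR noise: sqrt((S + n1)^2 + n2^2) with n1, n2 iid
    zero-mean Gaussians of standard deviation ``sigma``.  In background
    (S = 0) this is Rayleigh with mean sigma*sqrt(pi/2).  ``seed`` may
    be an int or a ``numpy.random.Generator``.
    """
    image = np.asarray(image, dtype=float)
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    if sigma == 0:
        return image.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, size=image.shape)
    n2 = rng.normal(0.0, sigma, size=image.shape)
    return np.sqrt((image + n1) ** 2 + n2**2)


def ir_protocol(tis=TI_SERIES_MS, tr=IR_REFERENCE_TR_MS, te=IR_REFERENCE_TE_MS) -> tuple:
    """Inversion-recovery reference protocol as SequenceParams entries."""
    return tuple(SequenceParams(tr=tr, te=te, ti=float(ti), label=f"IR TI={ti:g}") for ti in tis)


def me_protocol(tes=TE_SERIES_MS, tr=IR_REFERENCE_TR_MS) -> tuple:
    """Multi-echo reference protocol as SequenceParams entries."""
    return tuple(SequenceParams(tr=tr, te=float(te), label=f"ME TE={te:g}") for te in tes)


def simulate_acquisition(
    maps: QuantitativeMaps, protocol, sigma: float, seed=None
) -> AcquisitionSeries:
    """Simulate a magnitude acquisition series from quantitative maps.

    One volume per protocol entry; Rician noise of standard deviation
    ``sigma`` is applied voxelwise (independent across volumes, child
    streams spawned from ``seed``).  With sigma = 0 the volumes equal
    the noiseless synthesized signal exactly.
    """
    protocol = tuple(protocol)
    if not protocol:
        raise ValueError("protocol must contain at least one sequence")
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")

    tis = [s.ti for s in protocol]
    if all(ti is not None for ti in tis):
        mode, timings = "IR", [float(s.ti) for s in protocol]
    elif all(ti is None for ti in tis):
        mode, timings = "ME", [float(s.te) for s in protocol]
    else:
        raise ValueError("protocol mixes inversion and non-inversion sequences")

    volumes = [synthesize_weighted(maps, s) for s in protocol]
    if sigma > 0:
        seq = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
        streams = seq.spawn(len(volumes))
        volumes = [
            add_rician_noise(v, sigma, np.random.default_rng(s))
            for v, s in zip(volumes, streams)
        ]
    return AcquisitionSeries(
        volumes=np.stack(volumes),
        timing_list=timings,
        mode=mode,
        tr=float(protocol[0].tr),
    )


def bias_factors_from_table(table: pd.DataFrame, quantity: str) -> pd.DataFrame:
    """Per-concentration synthetic/reference bias factors for one quantity.

    The factor is mean(14 synthetic sessions) / reference, one row per
    concentration, sorted by reference time.
    """
    rows = table[table["quantity"] == quantity]
    syn_mean = rows[list(SYNTHETIC_COLUMNS)].to_numpy(float).mean(axis=1)
    out = pd.DataFrame(
        {
            "quantity": quantity,
            "concentration_mM": rows["concentration_mM"].to_numpy(float),
            "reference": rows["reference"].to_numpy(float),
            "factor": syn_mean / rows["reference"].to_numpy(float),
        }
    )
    return out.sort_values("reference", ignore_index=True)


def synthetic_scan_bias(true_values, bias_table, concentrations=None):
    """Apply the synthetic-scan bias model to true relaxation values.

    ``bias_table`` is a factor table from :func:`bias_factors_from_table`
    (or empty, in which case the output equals the input).  The
    multiplicative factor is linearly interpolated against concentration
    when ``concentrations`` is given, otherwise against the reference
    relaxation time; outside the tabulated range the nearest tabulated
    factor is used.
    """
    values = np.asarray(true_values, dtype=float)
    if bias_table is None or len(bias_table) == 0:
        out = values.copy()
        return out if out.ndim else float(out)
    if concentrations is not None:
        key = np.asarray(concentrations, dtype=float)
        order = np.argsort(bias_table["concentration_mM"].to_numpy(float))
        xp = bias_table["concentration_mM"].to_numpy(float)[order]
    else:
        key = values
        order = np.argsort(bias_table["reference"].to_numpy(float))
        xp = bias_table["reference"].to_numpy(float)[order]
    fp = bias_table["factor"].to_numpy(float)[order]
    factors = np.interp(key, xp, fp)
    out = values * factors
    return out if out.ndim else float(out)
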