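"""Synthetic multi-institution planning cohort with known ground truth.

The generator stands in for the clinical treatment plans of a multi-center
dummy run: 24 institutions each plan two breast-cancer cases (Case A,
right-sided after axillary dissection; Case S, left-sided after sentinel
biopsy) under two arms — whole-breast irradiation (WBI) and whole-breast
plus regional nodal irradiation (WBI+RNI) — with 6 of the 24 including the
internal mammary chain (IMN) in the nodal target.

Clinical plans come from beam-transport treatment-planning systems that are
out of scope here; only the downstream analysis needs exercising. The dose
model is therefore analytic: a sigmoid penumbra around the target volumes
with institution-specific field margins, a junction overdose bump where the
breast and nodal fields meet (three-field junctions routinely overdose, so
relative nodal doses above 1 must occur), a slowly decaying scatter floor
outside the fields, and multiplicative voxel noise. Fractionation schemes
are drawn from a fixed pool of seven clinically used prescriptions.

Everything is reproducible bit-exactly from one master seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.special import expit

from .core import (
    BinaryMask,
    DoseGrid,
    FractionationScheme,
    GridGeometry,
    NODAL_STATIONS,
    PlanRecord,
    StructureSet,
    extract_isodose_mask,
    read_structure_set,
    read_volume,
    write_structure_set,
    write_volume,
)
from .dosimetry import mean_structure_dose

__all__ = [
    "CaseSpec",
    "CASE_A",
    "CASE_S",
    "CohortConfig",
    "InstitutionParams",
    "PlanTruth",
    "GroundTruth",
    "Cohort",
    "default_scheme_pool",
    "generate_phantom",
    "generate_plan",
    "generate_cohort",
    "corrupt_mask",
    "write_cohort",
    "read_cohort",
]

ARMS = ("WBI", "WBI_RNI")


@dataclass(frozen=True)
class CaseSpec:
    """One dummy case: laterality and extent of axillary surgery."""

    case_id: str  # "A" | "S"
    laterality: str  # "right" | "left"
    axilla_surgery: str  # "ALND" | "SLNBx"

    def __post_init__(self) -> None:
        if self.case_id not in ("A", "S"):
            raise ValueError("case_id must be 'A' or 'S'")
        preset = {"A": ("right", "ALND"), "S": ("left", "SLNBx")}[self.case_id]
        if (self.laterality, self.axilla_surgery) != preset:
            raise ValueError(f"case {self.case_id} must be {preset}")


CASE_A = CaseSpec("A", "right", "ALND")
CASE_S = CaseSpec("S", "left", "SLNBx")


def default_scheme_pool() -> list[tuple[FractionationScheme, int]]:
    """The seven prescriptions used across the 24 institutions, with multiplicities."""
    return [
        (FractionationScheme(50.0, 25), 10),
        (FractionationScheme(50.4, 28), 8),
        (FractionationScheme(43.2, 16), 2),
        (FractionationScheme(41.6, 16), 1),
        (FractionationScheme(40.5, 15), 1),
        (FractionationScheme(40.05, 15), 1),
        (FractionationScheme(40.0, 16), 1),
    ]


def _default_grid() -> GridGeometry:
    return GridGeometry((96, 96, 96), (2.5, 2.5, 2.5), (0.0, 0.0, 0.0))


@dataclass
class CohortConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate the trial's dummy run: 24 institutions, 6 of which
    include IMN in the nodal target; the clinical fractionation pool; a
    7.5 mm median field margin with 3 mm inter-institution spread; 5 mm
    sigmoid penumbra; up to +15% junction overdose; a 3% scatter floor
    decaying over 40 mm; and 2% multiplicative dose noise.
    """

    n_institutions: int = 24
    n_imn_institutions: int = 6
    grid: GridGeometry = field(default_factory=_default_grid)
    scheme_pool: list[tuple[FractionationScheme, int]] = field(
        default_factory=default_scheme_pool
    )
    field_margin_mm: float = 12.5  # median margin from target to the 50% dose point
    field_margin_sd: float = 4.0  # mm, inter-institution spread
    field_margin_min: float = 5.0  # mm, floor on sampled margins
    rni_tangent_extra_mm: float = 5.0  # wider/high tangents used with nodal fields
    imn_field_extra_mm: float = 7.5  # deeper medial field when IMN is a target
    penumbra_width: float = 4.0  # mm, sigmoid dose-gradient scale
    junction_bump_range: tuple[float, float] = (0.05, 0.15)  # fraction of Rx
    scatter_floor: float = 0.03  # fraction of Rx at the field edge
    scatter_length: float = 40.0  # mm, scatter decay scale
    dose_noise_sd: float = 0.02  # multiplicative, fraction
    anatomy_jitter_sd: float = 1.5  # mm, per-structure centroid jitter
    rater_sensitivity: float = 0.95
    rater_specificity: float = 0.98
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_imn_institutions <= self.n_institutions:
            raise ValueError("n_imn_institutions must be <= n_institutions")
        if self.n_institutions < 2:
            raise ValueError("need at least 2 institutions")
        for prob in (self.rater_sensitivity, self.rater_specificity):
            if not 0.5 < prob <= 1.0:
                raise ValueError("rater probabilities must lie in (0.5, 1]")
        if self.penumbra_width <= 0 or self.scatter_length <= 0:
            raise ValueError("penumbra_width and scatter_length must be positive")


@dataclass(frozen=True)
class InstitutionParams:
    """Institution-specific planning habits, fixed across cases and arms."""

    institution_id: str
    scheme: FractionationScheme
    margin_mm: float
    junction_bump: float
    includes_imn: bool


@dataclass
class PlanTruth:
    """Generator-side truth for one plan (never read by analysis code)."""

    isodose_mask: BinaryMask  # true 90% isodose region of the generated dose
    station_mean_dose: dict[str, float]  # Gy, per structure


@dataclass
class GroundTruth:
    plan_truth: dict[tuple[str, str, str], PlanTruth]  # (inst, case, arm)
    rater_performance: dict[str, tuple[float, float]]  # inst -> (p, q)


@dataclass
class Cohort:
    config: CohortConfig
    institutions: list[InstitutionParams]
    structures: dict[str, StructureSet]  # case_id -> structures
    plans: list[PlanRecord]
    rater_masks: dict[tuple[str, str, str], BinaryMask]
    truth: GroundTruth | None = None

    def plan(self, institution_id: str, case_id: str, arm: str) -> PlanRecord:
        for p in self.plans:
            if (p.institution_id, p.case_id, p.arm) == (institution_id, case_id, arm):
                return p
        raise KeyError((institution_id, case_id, arm))


# ---------------------------------------------------------------------------
# Phantom anatomy
# ---------------------------------------------------------------------------

# Canonical right-sided anatomy in mm: center, semi-axes, optional half-space.
# Axes: x = right->left (mirrored for Case S), y = posterior->anterior,
# z = inferior->superior. The heart sits left of midline and is NOT mirrored,
# so for the left-sided case it lies nearer the breast.
_CANONICAL = {
    "HEART": ((140.0, 120.0, 95.0), (30.0, 27.0, 32.0), None),
    "LUNG_IPSI": ((70.0, 105.0, 125.0), (32.0, 40.0, 62.0), None),
    "BREAST": ((65.0, 150.0, 105.0), (42.0, 38.0, 48.0), ("y>=", 150.0)),
    "ALN_I": ((42.0, 138.0, 148.0), (12.0, 12.0, 12.0), None),
    "ALN_II": ((55.0, 134.0, 162.0), (10.0, 10.0, 10.0), None),
    "ALN_III": ((75.0, 125.0, 188.0), (9.0, 9.0, 9.0), None),
    "SCN": ((95.0, 130.0, 205.0), (10.0, 10.0, 10.0), None),
    "IMN": ((107.0, 145.0, 112.0), (6.0, 6.0, 30.0), None),
}
_MIRRORED = [n for n in _CANONICAL if n != "HEART"]
_CARVE_ORDER = ["HEART", "LUNG_IPSI", "BREAST", "ALN_I", "ALN_II", "ALN_III", "SCN", "IMN"]


def _ellipsoid(
    grid: GridGeometry,
    center: tuple[float, float, float],
    semi: tuple[float, float, float],
    halfspace: tuple[str, float] | None,
) -> np.ndarray:
    cx, cy, cz = grid.voxel_centers()
    x = ((cx - center[0]) / semi[0]) ** 2
    y = ((cy - center[1]) / semi[1]) ** 2
    z = ((cz - center[2]) / semi[2]) ** 2
    mask = x[:, None, None] + y[None, :, None] + z[None, None, :] <= 1.0
    if halfspace is not None:
        op, val = halfspace
        if op != "y>=":
            raise ValueError(f"unsupported halfspace {op!r}")
        mask &= (cy >= val)[None, :, None]
    return mask


def generate_phantom(
    case: CaseSpec, grid: GridGeometry, seed: int = 0, jitter_sd: float = 1.5
) -> StructureSet:
    """Deterministic-for-seed non-overlapping phantom anatomy for one case.

    Ellipsoidal structures with small seeded centroid jitter; structures are
    carved in a fixed order so all pairwise intersections are empty. Raises
    if any structure would leave the grid or end up empty.
    """
    rng = np.random.default_rng(seed)
    extent_lo = np.array(grid.origin)
    extent_hi = extent_lo + (np.array(grid.shape) - 1) * np.array(grid.spacing)
    mirror_x = extent_lo[0] + extent_hi[0]

    masks: dict[str, BinaryMask] = {}
    occupied = np.zeros(grid.shape, dtype=bool)
    for name in _CARVE_ORDER:
        center, semi, halfspace = _CANONICAL[name]
        jitter = rng.normal(0.0, jitter_sd, size=3)
        center = tuple(np.asarray(center) + jitter)
        if case.laterality == "left" and name in _MIRRORED:
            center = (mirror_x - center[0], center[1], center[2])
            if halfspace is not None:
                halfspace = (halfspace[0], halfspace[1])  # y-halfspace unaffected
        lo = np.asarray(center) - np.asarray(semi)
        hi = np.asarray(center) + np.asarray(semi)
        if np.any(lo < extent_lo) or np.any(hi > extent_hi):
            raise ValueError(f"structure {name} exceeds the grid extent")
        vals = _ellipsoid(grid, center, semi, halfspace) & ~occupied
        if not vals.any():
            raise ValueError(f"structure {name} is empty on this grid")
        occupied |= vals
        masks[name] = BinaryMask(grid, vals)
    return StructureSet(masks)


# ---------------------------------------------------------------------------
# Dose model
# ---------------------------------------------------------------------------

def _signed_distance(mask: np.ndarray, spacing: tuple[float, float, float]) -> np.ndarray:
    """Signed Euclidean distance to the mask surface: positive outside, negative inside."""
    outside = ndimage.distance_transform_edt(~mask, sampling=spacing)
    inside = ndimage.distance_transform_edt(mask, sampling=spacing)
    return (outside - inside).astype(np.float32)


def _target_names(arm: str, includes_imn: bool) -> tuple[str, ...]:
    if arm == "WBI":
        return ("BREAST",)
    if arm == "WBI_RNI":
        nodes = ["ALN_I", "ALN_II", "ALN_III", "SCN"]
        if includes_imn:
            nodes.append("IMN")
        return ("BREAST", *nodes)
    raise ValueError(f"unknown arm {arm!r}")


def _field_distances(
    anatomy: StructureSet,
    arm: str,
    includes_imn: bool,
    cache: dict | None = None,
) -> tuple[np.ndarray, np.ndarray | None, np.ndarray | None]:
    """Signed distances to breast, the ALN/SCN union (RNI) and IMN (if targeted)."""
    geom = anatomy.geometry
    spacing = geom.spacing

    def get(names: tuple[str, ...]) -> np.ndarray:
        key = names
        if cache is not None and key in cache:
            return cache[key]
        union = np.zeros(geom.shape, dtype=bool)
        for n in names:
            union |= anatomy[n].values
        sd = _signed_distance(union, spacing)
        if cache is not None:
            cache[key] = sd
        return sd

    sd_breast = get(("BREAST",))
    if arm == "WBI":
        return sd_breast, None, None
    sd_nodal = get(("ALN_I", "ALN_II", "ALN_III", "SCN"))
    sd_imn = get(("IMN",)) if includes_imn else None
    return sd_breast, sd_nodal, sd_imn


def generate_plan(
    anatomy: StructureSet,
    case: CaseSpec,
    arm: str,
    params: InstitutionParams,
    config: CohortConfig,
    seed: int,
    distance_cache: dict | None = None,
) -> tuple[PlanRecord, PlanTruth]:
    """One institution's analytic plan for one case and arm, plus its truth.

    dose = Rx * max(field, scatter) * noise, where field is a sigmoid of the
    signed distance to the target volumes shifted by the institution's
    margin; for WBI+RNI a junction bump proportional to the overlap of the
    breast and nodal fields is added (up to the configured fraction of Rx).
    """
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}")
    geom = anatomy.geometry
    w = config.penumbra_width
    margin = params.margin_mm
    sd_breast, sd_nodal, sd_imn = _field_distances(
        anatomy, arm, params.includes_imn, distance_cache
    )

    # WBI+RNI uses wider ("high") tangents, so the breast field reaches further
    breast_margin = margin + (config.rni_tangent_extra_mm if arm == "WBI_RNI" else 0.0)
    f_b = expit((breast_margin - sd_breast) / w)
    if sd_nodal is None:
        f = f_b
        field_sd = sd_breast
    else:
        f_n = expit((margin - sd_nodal) / w)
        if sd_imn is not None:
            # deeper medial field covering the parasternal chain
            f_imn = expit((margin + config.imn_field_extra_mm - sd_imn) / w)
            f_n = np.maximum(f_n, f_imn)
            sd_nodal = np.minimum(sd_nodal, sd_imn)
        f = np.maximum(f_b, f_n) + params.junction_bump * np.minimum(f_b, f_n)
        field_sd = np.minimum(sd_breast, sd_nodal)

    scatter = config.scatter_floor * np.exp(-np.maximum(field_sd, 0.0) / config.scatter_length)
    rel = np.maximum(f, scatter)
    rng = np.random.default_rng(seed)
    noise = np.maximum(1.0 + config.dose_noise_sd * rng.standard_normal(geom.shape), 0.0)
    values = (params.scheme.total_dose * rel * noise).astype(np.float32)
    dose = DoseGrid(geom, values)
    plan = PlanRecord(
        institution_id=params.institution_id,
        case_id=case.case_id,
        arm=arm,
        dose=dose,
        scheme=params.scheme,
        includes_imn=params.includes_imn if arm == "WBI_RNI" else False,
    )
    truth = PlanTruth(
        isodose_mask=extract_isodose_mask(dose, params.scheme, 0.9),
        station_mean_dose={
            name: mean_structure_dose(dose, mask) for name, mask in anatomy.items()
        },
    )
    return plan, truth


def corrupt_mask(
    mask: BinaryMask,
    sensitivity: float,
    specificity: float,
    rng: np.random.Generator,
) -> BinaryMask:
    """Voxelwise rater corruption: keep true voxels with probability
    ``sensitivity``, turn false voxels on with probability 1 - ``specificity``."""
    u = rng.random(mask.geometry.shape)
    vals = np.where(mask.values, u < sensitivity, u < (1.0 - specificity))
    return BinaryMask(mask.geometry, vals)


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

def _expand_pool(
    pool: list[tuple[FractionationScheme, int]], n: int
) -> list[FractionationScheme]:
    expanded = [s for s, mult in pool for _ in range(mult)]
    if not expanded:
        raise ValueError("empty scheme pool")
    while len(expanded) < n:
        expanded += expanded
    return expanded[:n]


def generate_cohort(config: CohortConfig) -> Cohort:
    """Full synthetic cohort: institutions x {A, S} x {WBI, WBI+RNI}.

    Scheme assignment, IMN-including subset, margins, junction bumps, plan
    noise and rater corruption all derive from ``config.seed``.
    """
    ss = np.random.SeedSequence(config.seed)
    assign_child, phantom_a_child, phantom_s_child, plan_ss = ss.spawn(4)
    assign_rng = np.random.default_rng(assign_child)
    n = config.n_institutions

    schemes = _expand_pool(config.scheme_pool, n)
    schemes = [schemes[i] for i in assign_rng.permutation(n)]
    imn_set = set(assign_rng.choice(n, size=config.n_imn_institutions, replace=False).tolist())
    margins = config.field_margin_mm + config.field_margin_sd * assign_rng.standard_normal(n)
    margins = np.maximum(margins, config.field_margin_min)
    lo, hi = config.junction_bump_range
    bumps = assign_rng.uniform(lo, hi, size=n)

    institutions = [
        InstitutionParams(
            institution_id=f"INST{i + 1:02d}",
            scheme=schemes[i],
            margin_mm=float(margins[i]),
            junction_bump=float(bumps[i]),
            includes_imn=i in imn_set,
        )
        for i in range(n)
    ]

    jit = config.anatomy_jitter_sd
    structures = {
        "A": generate_phantom(
            CASE_A, config.grid, seed=int(phantom_a_child.generate_state(1)[0] % (2**31)),
            jitter_sd=jit,
        ),
        "S": generate_phantom(
            CASE_S, config.grid, seed=int(phantom_s_child.generate_state(1)[0] % (2**31)),
            jitter_sd=jit,
        ),
    }
    cases = {"A": CASE_A, "S": CASE_S}

    plans: list[PlanRecord] = []
    rater_masks: dict[tuple[str, str, str], BinaryMask] = {}
    plan_truth: dict[tuple[str, str, str], PlanTruth] = {}
    caches = {"A": {}, "S": {}}
    seeds = plan_ss.generate_state(8 * n)  # noise + rater seed per plan
    k = 0
    for inst in institutions:
        for case_id in ("A", "S"):
            for arm in ARMS:
                plan, truth = generate_plan(
                    structures[case_id],
                    cases[case_id],
                    arm,
                    inst,
                    config,
                    seed=int(seeds[k] % (2**31)),
                    distance_cache=caches[case_id],
                )
                rater_rng = np.random.default_rng(int(seeds[k + 1] % (2**31)))
                key = (inst.institution_id, case_id, arm)
                plans.append(plan)
                plan_truth[key] = truth
                rater_masks[key] = corrupt_mask(
                    truth.isodose_mask,
                    config.rater_sensitivity,
                    config.rater_specificity,
                    rater_rng,
                )
                k += 2

    truth = GroundTruth(
        plan_truth=plan_truth,
        rater_performance={
            inst.institution_id: (config.rater_sensitivity, config.rater_specificity)
            for inst in institutions
        },
    )
    return Cohort(
        config=config,
        institutions=institutions,
        structures=structures,
        plans=plans,
        rater_masks=rater_masks,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# On-disk manifest
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write NIfTI volumes plus a JSON manifest; ground truth in a separate JSON."""
    out = Path(out_dir)
    (out / "doses").mkdir(parents=True, exist_ok=True)
    (out / "raters").mkdir(exist_ok=True)
    (out / "truth_masks").mkdir(exist_ok=True)

    structure_maps = {}
    for case_id, sset in cohort.structures.items():
        structure_maps[case_id] = write_structure_set(sset, out / "structures" / case_id)

    plan_entries = []
    for plan in cohort.plans:
        key = (plan.institution_id, plan.case_id, plan.arm)
        stem = f"{plan.institution_id}_{plan.case_id}_{plan.arm}"
        dose_path = f"doses/{stem}.nii.gz"
        rater_path = f"raters/{stem}.nii.gz"
        write_volume(plan.dose, out / dose_path)
        write_volume(cohort.rater_masks[key], out / rater_path)
        plan_entries.append(
            {
                "institution_id": plan.institution_id,
                "case_id": plan.case_id,
                "arm": plan.arm,
                "scheme": {
                    "total_dose": plan.scheme.total_dose,
                    "n_fractions": plan.scheme.n_fractions,
                },
                "includes_imn": plan.includes_imn,
                "dose_path": dose_path,
                "rater_path": rater_path,
            }
        )

    geom = cohort.config.grid
    manifest = {
        "n_institutions": cohort.config.n_institutions,
        "n_imn_institutions": cohort.config.n_imn_institutions,
        "seed": cohort.config.seed,
        "grid": {"shape": geom.shape, "spacing": geom.spacing, "origin": geom.origin},
        "structures": structure_maps,
        "plans": plan_entries,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    if cohort.truth is not None:
        truth_json = {"rater_performance": {}, "plans": []}
        for inst, (p, q) in sorted(cohort.truth.rater_performance.items()):
            truth_json["rater_performance"][inst] = {"sensitivity": p, "specificity": q}
        for key, pt in sorted(cohort.truth.plan_truth.items()):
            stem = "_".join(key)
            mask_path = f"truth_masks/{stem}.nii.gz"
            write_volume(pt.isodose_mask, out / mask_path)
            truth_json["plans"].append(
                {
                    "institution_id": key[0],
                    "case_id": key[1],
                    "arm": key[2],
                    "isodose_mask_path": mask_path,
                    "station_mean_dose": {
                        k: float(v) for k, v in sorted(pt.station_mean_dose.items())
                    },
                }
            )
        (out / "ground_truth.json").write_text(json.dumps(truth_json, indent=2, sort_keys=True))
    return out / "manifest.json"


def read_cohort(directory: str | Path, load_truth: bool = False) -> Cohort:
    """Load a cohort written by :func:`write_cohort` from its manifest."""
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest found at {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    grid = GridGeometry(
        tuple(manifest["grid"]["shape"]),
        tuple(manifest["grid"]["spacing"]),
        tuple(manifest["grid"]["origin"]),
    )
    config = CohortConfig(
        n_institutions=manifest["n_institutions"],
        n_imn_institutions=manifest["n_imn_institutions"],
        grid=grid,
        seed=manifest["seed"],
    )
    structures = {
        case_id: read_structure_set(directory / "structures" / case_id, mapping)
        for case_id, mapping in manifest["structures"].items()
    }

    plans: list[PlanRecord] = []
    rater_masks: dict[tuple[str, str, str], BinaryMask] = {}
    inst_info: dict[str, dict] = {}
    for entry in manifest["plans"]:
        dose_path = directory / entry["dose_path"]
        if not dose_path.exists():
            raise FileNotFoundError(f"dose volume missing: {dose_path}")
        dose = read_volume(dose_path, kind="dose")
        scheme = FractionationScheme(
            entry["scheme"]["total_dose"], entry["scheme"]["n_fractions"]
        )
        plan = PlanRecord(
            institution_id=entry["institution_id"],
            case_id=entry["case_id"],
            arm=entry["arm"],
            dose=dose,
            scheme=scheme,
            includes_imn=entry["includes_imn"],
        )
        plans.append(plan)
        rater_path = directory / entry.get("rater_path", "")
        if entry.get("rater_path") and rater_path.exists():
            key = (plan.institution_id, plan.case_id, plan.arm)
            rater_masks[key] = read_volume(rater_path, kind="mask")
        info = inst_info.setdefault(
            entry["institution_id"],
            {"scheme": scheme, "includes_imn": False},
        )
        if entry["arm"] == "WBI_RNI":
            info["includes_imn"] = entry["includes_imn"]

    institutions = [
        InstitutionParams(
            institution_id=inst,
            scheme=info["scheme"],
            margin_mm=float("nan"),  # not recoverable from disk; generator-internal
            junction_bump=float("nan"),
            includes_imn=info["includes_imn"],
        )
        for inst, info in sorted(inst_info.items())
    ]

    truth = None
    truth_path = directory / "ground_truth.json"
    if load_truth and truth_path.exists():
        tj = json.loads(truth_path.read_text())
        plan_truth = {}
        for entry in tj["plans"]:
            key = (entry["institution_id"], entry["case_id"], entry["arm"])
            plan_truth[key] = PlanTruth(
                isodose_mask=read_volume(directory / entry["isodose_mask_path"], kind="mask"),
                station_mean_dose=entry["station_mean_dose"],
            )
        truth = GroundTruth(
            plan_truth=plan_truth,
            rater_performance={
                inst: (d["sensitivity"], d["specificity"])
                for inst, d in tj["rater_performance"].items()
            },
        )
    return Cohort(
        config=config,
        institutions=institutions,
        structures=structures,
        plans=plans,
        rater_masks=rater_masks,
        truth=truth,
    )
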