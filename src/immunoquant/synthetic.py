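"""Seeded synthetic-data generators with exact ground truth.

No raw micrographs are distributed with the assays this package quantifies,
so every pipeline stage is exercised on rendered images whose geometry is
known exactly.  The renderer uses fixed intensity bands per structure
(background 10, capsule 110, bead/cell 220 on a 0-255 scale) with optional
additive Gaussian noise; capsules are concentric annular arcs so that the
analytic area and angle oracles hold by construction.  Every generator is a
pure function of its parameters and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from skimage.draw import disk as draw_disk
from skimage.draw import polygon as draw_polygon

from .beads import DEFAULT_SCHEME, GradeScheme
from .cells import CellRecord
from .errors import ConfigError, DomainError, PlacementError, SizingError

BACKGROUND_LEVEL = 10.0
CAPSULE_LEVEL = 110.0
BEAD_LEVEL = 220.0
CELL_LEVEL = 180.0
NUCLEUS_LEVEL = 200.0
SPOT_LEVEL = 220.0


# ---------------------------------------------------------------------------
# bead images


@dataclass(frozen=True)
class BeadTruth:
    """Ground-truth geometry of one rendered bead."""

    bead_radius: float = 40.0  # px
    coverage_deg: float = 0.0  # [0, 360]
    thickness_ratio: float = 0.0  # annulus outer radius = R*(1+ratio)
    noise_sd: float = 0.0  # intensity units on the 0-255 scale
    pixel_size: float = 1.0  # um/px
    seed: int = 0
    arc_start_deg: float = 0.0  # CCW from +x axis
    bead_center: "tuple | None" = None  # (row, col); canvas centre if None

    def __post_init__(self) -> None:
        if not (0.0 <= self.coverage_deg <= 360.0):
            raise DomainError("coverage_deg must be in [0, 360]")
        if self.thickness_ratio < 0:
            raise DomainError("thickness_ratio must be >= 0")
        if self.bead_radius <= 0:
            raise DomainError("bead_radius must be positive")
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be >= 0")

    @property
    def outer_radius(self) -> float:
        return self.bead_radius * (1.0 + self.thickness_ratio)

    def footprint_area_px(self) -> float:
        """Analytic bead+capsule footprint area in px^2."""
        r, ro = self.bead_radius, self.outer_radius
        return math.pi * r**2 + (self.coverage_deg / 360.0) * math.pi * (ro**2 - r**2)

    def area_fraction(self) -> float:
        return self.coverage_deg / 360.0

    def formula_thickness(self) -> float:
        """T as the grading formula sees it: sqrt(footprint/pi)/R - 1."""
        return math.sqrt(self.footprint_area_px() / math.pi) / self.bead_radius - 1.0

    def grades(self, scheme: GradeScheme = DEFAULT_SCHEME) -> "tuple[int, int]":
        return (
            scheme.assign(self.area_fraction(), "area"),
            scheme.assign(self.formula_thickness(), "thickness"),
        )


def generate_bead_image(
    truth: BeadTruth, image_shape: "tuple | None" = None
) -> "tuple[np.ndarray, BeadTruth]":
    """Render one bead (bright disk) with an annular capsule arc.

    The canvas defaults to a square of side ceil(2.2 * outer diameter / 2) *2
    with the bead centred; an explicit shape too small for the geometry is a
    sizing error.  Returns the float image (0-255 scale) and the truth with
    the realised centre filled in.
    """
    if image_shape is None:
        side = int(math.ceil(2.2 * truth.outer_radius)) | 1
        image_shape = (side, side)
    h, w = image_shape
    if truth.bead_center is None:
        center = ((h - 1) / 2.0, (w - 1) / 2.0)
    else:
        center = truth.bead_center
    cr, cc = center
    ro = truth.outer_radius
    if cr - ro < 0 or cc - ro < 0 or cr + ro > h - 1 or cc + ro > w - 1:
        raise SizingError(
            f"bead outer radius {ro:.1f} px does not fit on a {h}x{w} canvas"
        )

    rows, cols = np.mgrid[0:h, 0:w]
    dist = np.hypot(rows - cr, cols - cc)
    image = np.full((h, w), BACKGROUND_LEVEL, dtype=float)

    if truth.coverage_deg > 0 and truth.thickness_ratio > 0:
        # CCW angle from +x axis; image rows grow downward
        ang = np.degrees(np.arctan2(-(rows - cr), cols - cc)) % 360.0
        rel = (ang - truth.arc_start_deg) % 360.0
        in_arc = rel <= truth.coverage_deg
        if truth.coverage_deg >= 360.0:
            in_arc = np.ones_like(in_arc)
        annulus = (dist > truth.bead_radius) & (dist <= ro) & in_arc
        image[annulus] = CAPSULE_LEVEL
    image[dist <= truth.bead_radius] = BEAD_LEVEL

    if truth.noise_sd > 0:
        rng = np.random.default_rng(truth.seed)
        image = image + rng.normal(0.0, truth.noise_sd, size=image.shape)
    return image, replace(truth, bead_center=center)


def _sample_dist(spec, rng: np.random.Generator, n: int) -> np.ndarray:
    """Sample a distribution spec: number (degenerate), ('uniform', lo, hi),
    ('normal', mu, sd), or ('degenerate', v)."""
    if isinstance(spec, (int, float)):
        return np.full(n, float(spec))
    try:
        kind = spec[0]
    except (TypeError, IndexError):
        raise ConfigError(f"invalid distribution spec: {spec!r}") from None
    if kind == "degenerate" and len(spec) == 2:
        return np.full(n, float(spec[1]))
    if kind == "uniform" and len(spec) == 3:
        lo, hi = float(spec[1]), float(spec[2])
        if hi < lo:
            raise ConfigError(f"uniform bounds reversed: {spec!r}")
        return rng.uniform(lo, hi, size=n)
    if kind == "normal" and len(spec) == 3:
        mu, sd = float(spec[1]), float(spec[2])
        if sd < 0:
            raise ConfigError(f"negative sd: {spec!r}")
        return rng.normal(mu, sd, size=n)
    raise ConfigError(f"invalid distribution spec: {spec!r}")


def generate_bead_cohort(
    n_beads: int,
    coverage_dist=("uniform", 0.0, 360.0),
    thickness_dist=("uniform", 0.2, 1.2),
    seed: int = 0,
    bead_radius: float = 40.0,
    noise_sd: float = 0.0,
) -> "list[tuple[np.ndarray, BeadTruth]]":
    """Render a cohort of independent single-bead images.

    Coverage values are clipped to [0, 360] and thickness ratios floored at
    0 after sampling, so normal specs near the boundary remain valid.
    """
    if n_beads < 1:
        raise DomainError("n_beads must be >= 1")
    rng = np.random.default_rng(seed)
    coverages = np.clip(_sample_dist(coverage_dist, rng, n_beads), 0.0, 360.0)
    thicknesses = np.maximum(_sample_dist(thickness_dist, rng, n_beads), 0.0)
    starts = rng.uniform(0.0, 360.0, size=n_beads)
    seeds = rng.integers(0, 2**31 - 1, size=n_beads)
    out = []
    for i in range(n_beads):
        truth = BeadTruth(
            bead_radius=bead_radius,
            coverage_deg=float(coverages[i]),
            thickness_ratio=float(thicknesses[i]),
            noise_sd=noise_sd,
            seed=int(seeds[i]),
            arc_start_deg=float(starts[i]),
        )
        out.append(generate_bead_image(truth))
    return out


# ---------------------------------------------------------------------------
# hemocyte fields


@dataclass(frozen=True)
class FieldTruth:
    """Ground-truth composition of one rendered hemocyte field."""

    n_cells: int = 500
    spread_fraction: float = 0.6
    type_mix: tuple = (0.5, 0.4, 0.1)  # plasmatocyte, granulocyte, other
    phagocytic_fraction: float = 0.0
    mean_spots: float = 2.0  # expected engulfed bacteria per phagocytic cell
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("spread_fraction", "phagocytic_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise DomainError(f"{name} must be in [0, 1]")
        if abs(sum(self.type_mix) - 1.0) > 1e-9 or any(f < 0 for f in self.type_mix):
            raise DomainError("type_mix fractions must be >= 0 and sum to 1")
        if self.n_cells < 0:
            raise DomainError("n_cells must be >= 0")
        if self.mean_spots < 1.0:
            raise DomainError("mean_spots must be >= 1 (phagocytic cells carry >= 1)")


def _star_polygon(
    center, r0: float, arms: int, amp: float, phase: float, n_vert: int = 90
):
    theta = np.linspace(0.0, 2.0 * np.pi, n_vert, endpoint=False)
    r = r0 * (1.0 + amp * np.cos(arms * theta + phase))
    rows = center[0] + r * np.sin(theta)
    cols = center[1] + r * np.cos(theta)
    return rows, cols


def _place_centers(
    rng: np.random.Generator, n: int, shape, margin: float, min_sep: float
) -> np.ndarray:
    """Rejection-sample non-overlapping centres; bounded retries."""
    h, w = shape
    if h - 2 * margin <= 0 or w - 2 * margin <= 0:
        raise PlacementError("field too small for the requested cell size")
    centers = np.empty((0, 2))
    attempts = 0
    max_attempts = 300 * max(n, 1)
    while len(centers) < n:
        attempts += 1
        if attempts > max_attempts:
            raise PlacementError(
                f"could only place {len(centers)}/{n} cells without overlap"
            )
        cand = np.array(
            [rng.uniform(margin, h - 1 - margin), rng.uniform(margin, w - 1 - margin)]
        )
        if len(centers) and np.min(np.hypot(*(centers - cand).T)) < min_sep:
            continue
        centers = np.vstack([centers, cand])
    return centers


def generate_hemocyte_field(
    truth: FieldTruth, image_size: "tuple" = (1536, 1536)
) -> "tuple[np.ndarray, np.ndarray, np.ndarray, pd.DataFrame]":
    """Render DIC, nuclei, and bacteria channels plus a ground-truth table.

    Spread cells are star silhouettes (5-ish arms, low circularity); round
    cells are disks.  Phagocytic cells carry k ~ 1 + Poisson(mean_spots - 1)
    bacteria spots inside their body; non-phagocytic cells carry none.
    The returned table has one row per cell: row, col, type, spread,
    engulfed_count, body_radius.
    """
    rng = np.random.default_rng(truth.seed)
    h, w = image_size
    r0 = rng.uniform(8.0, 12.0, size=truth.n_cells)
    arm_amp = 0.55
    max_extent = (r0 * (1.0 + arm_amp)).max() if truth.n_cells else 0.0
    centers = _place_centers(
        rng, truth.n_cells, image_size, margin=max_extent + 3.0,
        min_sep=2.0 * max_extent + 4.0,
    )

    types = rng.choice(
        ["plasmatocyte", "granulocyte", "other"], size=truth.n_cells, p=truth.type_mix
    )
    spread = rng.random(truth.n_cells) < truth.spread_fraction
    phago = rng.random(truth.n_cells) < truth.phagocytic_fraction
    n_spots = np.where(phago, 1 + rng.poisson(truth.mean_spots - 1.0, truth.n_cells), 0)

    dic = np.full(image_size, BACKGROUND_LEVEL, dtype=float)
    nuclei = np.full(image_size, BACKGROUND_LEVEL, dtype=float)
    bacteria = np.full(image_size, BACKGROUND_LEVEL, dtype=float)

    rows_out = []
    for i in range(truth.n_cells):
        c = centers[i]
        if spread[i]:
            arms = int(rng.integers(4, 7))
            phase = rng.uniform(0, 2 * np.pi)
            pr, pc = _star_polygon(c, r0[i], arms, arm_amp, phase)
            rr, cc = draw_polygon(pr, pc, shape=image_size)
        else:
            rr, cc = draw_disk(c, r0[i], shape=image_size)
        dic[rr, cc] = CELL_LEVEL
        nr, nc = draw_disk(c, max(2.5, 0.35 * r0[i]), shape=image_size)
        nuclei[nr, nc] = NUCLEUS_LEVEL

        # spots anywhere inside the silhouette with a 3 px margin, kept
        # >= 7 px apart so each remains a resolvable intensity peak
        placed = 0
        spot_pos: list[np.ndarray] = []
        tries = 0
        while placed < n_spots[i] and tries < 400:
            tries += 1
            ang = rng.uniform(0, 2 * np.pi)
            if spread[i]:
                rmax = r0[i] * (1.0 + arm_amp * math.cos(arms * ang + phase)) - 3.0
            else:
                rmax = r0[i] - 3.0
            if rmax <= 0:
                continue
            rad = rmax * math.sqrt(rng.uniform())
            pos = c + rad * np.array([math.sin(ang), math.cos(ang)])
            if spot_pos and np.min(np.hypot(*(np.array(spot_pos) - pos).T)) < 7.0:
                continue
            sr, sc = draw_disk(pos, 2.0, shape=image_size)
            bacteria[sr, sc] = SPOT_LEVEL
            spot_pos.append(pos)
            placed += 1

        rows_out.append(
            {
                "row": c[0],
                "col": c[1],
                "type": types[i],
                "spread": bool(spread[i]),
                "engulfed_count": placed,
                "body_radius": r0[i],
            }
        )

    if truth.noise_sd > 0:
        for chan in (dic, nuclei, bacteria):
            chan += rng.normal(0.0, truth.noise_sd, size=image_size)
    return dic, nuclei, bacteria, pd.DataFrame(rows_out)


def truth_records(table: pd.DataFrame) -> "list[CellRecord]":
    """Ground-truth table → CellRecord list (for oracle-side computations)."""
    return [
        CellRecord(
            cell_id=i + 1,
            type=str(r["type"]),
            spread=bool(r["spread"]),
            engulfed_count=int(r["engulfed_count"]),
            centroid=(float(r["row"]), float(r["col"])),
        )
        for i, r in table.iterrows()
    ]


# ---------------------------------------------------------------------------
# fluorescence readings and docking tables


def generate_factin_readings(
    group_means,
    cv: float = 0.1,
    n_per_group: int = 4,
    blank_mean: float = 100.0,
    seed: int = 0,
    group_labels: "list[str] | None" = None,
) -> pd.DataFrame:
    """Replicate spectrofluorometer readings around group means.

    Readings are lognormal with the requested mean and coefficient of
    variation (cv = 0 degenerates to the exact mean), so they stay positive.
    A ``blank`` group with ``blank_mean`` is always included.  The default
    four replicates per group matches the assay's biological replication.
    """
    if not (0.0 <= cv < 1.0):
        raise DomainError("cv must be in [0, 1)")
    if blank_mean <= 0 or any(m <= 0 for m in group_means):
        raise DomainError("group and blank means must be positive")
    if n_per_group < 1:
        raise DomainError("n_per_group must be >= 1")
    if group_labels is None:
        group_labels = [f"group{i}" for i in range(len(group_means))]
    rng = np.random.default_rng(seed)
    rows = []
    for label, mean in list(zip(group_labels, group_means)) + [("blank", blank_mean)]:
        if cv == 0.0:
            vals = np.full(n_per_group, float(mean))
        else:
            sigma2 = math.log(1.0 + cv**2)
            mu = math.log(mean) - sigma2 / 2.0
            vals = rng.lognormal(mu, math.sqrt(sigma2), size=n_per_group)
        rows += [{"group": label, "replicate": j, "intensity": float(v)}
                 for j, v in enumerate(vals)]
    return pd.DataFrame(rows)


def generate_docking_table(
    ligands,
    energy_ranges,
    n_conformers: int = 10,
    seed: int = 0,
) -> "tuple[pd.DataFrame, dict]":
    """Per-ligand conformer energies uniform in the stated interval.

    ``energy_ranges`` maps ligand → (low, high) in kcal/mol; a degenerate
    interval pins every conformer to that energy.  Returns the pose table
    and the ground-truth per-ligand minimum.
    """
    ligands = list(ligands)
    if not ligands:
        raise DomainError("ligand list must be nonempty")
    if n_conformers < 1:
        raise DomainError("n_conformers must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    truth_min = {}
    for lig in ligands:
        lo, hi = energy_ranges[lig]
        if not (math.isfinite(lo) and math.isfinite(hi)) or hi < lo:
            raise ConfigError(f"invalid energy range for {lig!r}: {(lo, hi)}")
        energies = rng.uniform(lo, hi, size=n_conformers)
        truth_min[lig] = float(energies.min())
        rows += [
            {"ligand": lig, "conformer": j + 1, "binding_energy_kcal_mol": float(e)}
            for j, e in enumerate(energies)
        ]
    return pd.DataFrame(rows), truth_min
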