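"""Ground-truthed synthetic inputs for every analysis stage.

Three generators, all pure functions of a seed-bearing config:

* :func:`make_assembly` — a spherical cage of pseudo-atoms around a
  lysine NZ site with a circular aperture of known half-angle; whether a
  tangent probe fits through the aperture has a closed-form answer, so
  the accessibility procedure can be certified against exact truth.
* :func:`make_glygly_table` — a SILAC GlyGly site table with the
  experimental design used for this kind of screen: three biological
  replicates, one of them a label swap, log-normal measurement noise,
  and a planted fraction of sites whose occupancy drops, concentrated in
  the ribosomal category.
* :func:`make_ibaq_table` — per-protein iBAQ abundances for paired
  mutant/wild-type insoluble fractions with a planted accumulating
  subset.

The defaults mirror the study design the package targets: ~10% of
quantified sites ribosomal, ~15% of sites affected, a 4-fold planted
occupancy decrease, 0.3 log2-units of replicate noise, 1270 proteins in
the insoluble-fraction table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .probe_access import R_NZ, sphere_directions
from .structure_io import Atom, AssemblyState, LysineSite

#: pseudo-atom radius used for cage fixtures (carbon-like, closed-form friendly)
CAGE_ATOM_RADIUS = 1.70


@dataclass(frozen=True)
class SimConfig:
    """Configuration for all generators; identical seed => identical output."""

    seed: int = 0
    # proteomics table shape
    n_sites: int = 1000
    frac_ribosomal: float = 0.10
    frac_affected: float = 0.15
    effect_log2: float = 2.0
    noise_sd_log2: float = 0.3
    n_replicates: int = 3
    swap_replicates: frozenset[str] = field(default_factory=lambda: frozenset({"3"}))
    ribosomal_odds: float = 8.0
    # iBAQ table
    n_proteins: int = 1270
    ibaq_frac_affected: float = 0.10
    ibaq_noise_sd: float = 1.0e6
    ibaq_shift_multiple: float = 5.0
    # assembly cage
    cage_radius: float = 6.0
    aperture_half_angle_deg: float = 90.0
    obstacle_spacing: float = 1.0
    probe_radius: float = 25.0

    def __post_init__(self) -> None:
        for name in ("frac_ribosomal", "frac_affected", "ibaq_frac_affected"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not 0.0 <= self.aperture_half_angle_deg <= 180.0:
            raise ValueError("aperture_half_angle_deg must be in [0, 180]")
        if self.obstacle_spacing >= self.cage_radius:
            raise ValueError("obstacle spacing must be smaller than the cage radius")


# ---------------------------------------------------------------------------
# geometric fixtures


def critical_half_angle_deg(
    cage_radius: float,
    probe_radius: float,
    atom_radius: float = CAGE_ATOM_RADIUS,
    nz_radius: float = R_NZ,
) -> float:
    """Closed-form critical aperture half-angle for a tangent probe.

    The probe centre sits at distance ``d = probe_radius + nz_radius``
    from the caged NZ atom. Along the aperture axis, the nearest cage
    atoms are those on the aperture rim, at angular distance alpha (the
    aperture half-angle); the centre-to-rim distance is
    ``sqrt(d^2 + r_c^2 - 2 d r_c cos(alpha))``. The axis direction is
    clear — and by monotonicity of the rim distance in alpha, it is the
    best direction — exactly when that distance reaches the clash
    threshold ``probe_radius + atom_radius``. Solving at equality gives
    the flip angle. Returns 180 when no aperture can admit the probe and
    0 when even a closed cage cannot exclude it (the latter only for
    degenerate radii).
    """
    d = probe_radius + nz_radius
    rc = cage_radius
    thr = probe_radius + atom_radius
    cos_alpha = (d * d + rc * rc - thr * thr) / (2.0 * d * rc)
    if cos_alpha > 1.0:
        # nearest possible cage atom is already beyond the clash threshold:
        # the wall can never block the probe
        return 0.0
    if cos_alpha < -1.0:
        # no aperture short of removing the cage admits the probe
        return 180.0
    return math.degrees(math.acos(cos_alpha))


def _cage_points(radius: float, spacing: float) -> np.ndarray:
    """Quasi-uniform points on a sphere with approximately given spacing."""
    n = max(8, int(round(4.0 * math.pi * radius**2 / spacing**2)))
    return radius * sphere_directions(n)


def make_assembly(cfg: SimConfig, name: str = "cage") -> tuple[AssemblyState, LysineSite, bool]:
    """Spherical pseudo-atom cage with an aperture; returns exact truth.

    The NZ site sits at the origin; cage atoms occupy the sphere of
    ``cage_radius`` except for a circular aperture of
    ``aperture_half_angle_deg`` around +z. Truth: the site is accessible
    iff the aperture half-angle is at least the closed-form critical
    angle. The generator refuses cages whose discretization gaps are
    wide enough to admit the probe through a nominally closed wall —
    such a fixture would have ambiguous truth.
    """
    alpha = cfg.aperture_half_angle_deg
    crit = critical_half_angle_deg(cfg.cage_radius, cfg.probe_radius)
    # widest angular half-gap of the discrete cage; a wall leaks if a gap
    # between neighbouring atoms subtends more than the critical angle
    gap_half_angle = math.degrees(cfg.obstacle_spacing / cfg.cage_radius)
    if gap_half_angle >= crit:
        raise ValueError(
            f"cage spacing {cfg.obstacle_spacing} A at radius {cfg.cage_radius} A "
            f"leaks (gap half-angle {gap_half_angle:.1f} deg >= critical "
            f"{crit:.1f} deg): ambiguous truth"
        )
    pts = _cage_points(cfg.cage_radius, cfg.obstacle_spacing)
    polar = np.degrees(np.arccos(np.clip(pts[:, 2] / cfg.cage_radius, -1, 1)))
    pts = pts[polar > alpha]

    atoms = [
        Atom(
            position=(0.0, 0.0, 0.0),
            element="N",
            vdw_radius=R_NZ,
            chain_id="A",
            residue_number=1,
            residue_name="LYS",
            atom_name="NZ",
        )
    ]
    for i, p in enumerate(pts, start=2):
        atoms.append(
            Atom(
                position=tuple(float(x) for x in p),
                element="C",
                vdw_radius=CAGE_ATOM_RADIUS,
                chain_id="B",
                residue_number=i,
                residue_name="CAG",
                atom_name="C",
            )
        )
    state = AssemblyState(
        name=name,
        atoms=atoms,
        chain_map={"A": "target", "B": "cage"},
        source=f"synthetic cage r={cfg.cage_radius} aperture={alpha}",
    )
    site = LysineSite(
        protein="target", chain_id="A", residue_number=1, nz_position=(0.0, 0.0, 0.0)
    )
    accessible_truth = alpha >= crit
    return state, site, accessible_truth


# ---------------------------------------------------------------------------
# proteomics tables


def make_glygly_table(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """SILAC GlyGly site table with planted occupancy decreases.

    Returns ``(table, truth)``. The table is long-format (protein,
    position, category, replicate, ratio, swap) as read by
    ``glygly_quant.read_site_table``; ratios of swap replicates are
    emitted inverted with the swap flag set, exactly as a label-swap run
    reports them. Truth holds each site's category, planted log2 effect
    and affected flag.

    Affected sites are concentrated in the ribosomal category with odds
    ``ribosomal_odds``: the per-site affection probability is scaled so
    the overall affected fraction stays at ``frac_affected``.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_sites
    ribosomal = rng.random(n) < cfg.frac_ribosomal
    # odds-weighted affection probabilities, normalised to the target fraction
    w = np.where(ribosomal, cfg.ribosomal_odds, 1.0)
    p_affect = cfg.frac_affected * w / np.mean(w)
    p_affect = np.clip(p_affect, 0.0, 1.0)
    affected = rng.random(n) < p_affect

    reps = [str(i + 1) for i in range(cfg.n_replicates)]
    rows = []
    truth_rows = []
    for i in range(n):
        protein = f"{'RPL' if ribosomal[i] else 'YPR'}{i:04d}"
        category = "large" if ribosomal[i] else "nonribosomal"
        position = int(rng.integers(5, 400))
        mu = -cfg.effect_log2 if affected[i] else 0.0
        truth_rows.append(
            {
                "protein": protein,
                "position": position,
                "category": category,
                "affected": bool(affected[i]),
                "true_log2": mu,
            }
        )
        for rep in reps:
            log2_ratio = mu + rng.normal(0.0, cfg.noise_sd_log2)
            ratio = 2.0 ** log2_ratio
            swap = rep in cfg.swap_replicates
            rows.append(
                {
                    "protein": protein,
                    "position": position,
                    "category": category,
                    "replicate": rep,
                    "ratio": 1.0 / ratio if swap else ratio,
                    "swap": int(swap),
                }
            )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


def make_ibaq_table(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired mutant/WT iBAQ abundances with planted accumulators.

    Baseline abundances are log-normal (median 1e7, one decade spread),
    per-replicate measurement noise is additive Gaussian with
    ``ibaq_noise_sd``, and a planted fraction of proteins receives a
    mutant-side shift of ``ibaq_shift_multiple * ibaq_noise_sd``.
    Returns ``(table, truth)``; the wide table has one row per protein
    with ``ibaq_mut_<rep>`` / ``ibaq_wt_<rep>`` columns.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    n = cfg.n_proteins
    planted = np.zeros(n, dtype=bool)
    k = int(round(cfg.ibaq_frac_affected * n))
    planted[rng.choice(n, size=k, replace=False)] = True
    baseline = 10.0 ** rng.normal(7.0, 1.0, size=n)
    shift = cfg.ibaq_shift_multiple * cfg.ibaq_noise_sd
    reps = [str(i + 1) for i in range(cfg.n_replicates)]
    rows = []
    for i in range(n):
        row = {"protein": f"P{i:05d}"}
        for rep in reps:
            wt = baseline[i] + rng.normal(0.0, cfg.ibaq_noise_sd)
            mut = baseline[i] + (shift if planted[i] else 0.0) + rng.normal(
                0.0, cfg.ibaq_noise_sd
            )
            row[f"ibaq_wt_{rep}"] = max(wt, 0.0)
            row[f"ibaq_mut_{rep}"] = max(mut, 0.0)
        rows.append(row)
    truth = pd.DataFrame(
        {"protein": [f"P{i:05d}" for i in range(n)], "planted": planted}
    )
    return pd.DataFrame(rows), truth
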