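"""Synthetic-data generators with planted ground truth.

The study's raw plates and TIRF movies are not deposited, so every pipeline
stage here is validated against generated data whose statistical structure
matches what the stage assumes:

* ``gen_screen`` — 384-well plates in triplicate with log-normal null
  intensities, control wells realising the positive-control (DNM2) effect,
  and a sparse set of planted uptake-reducing genes with effects stated in
  plate-MAD units.
* ``gen_followup`` — deconvolution tables (4 siRNAs × 2 sets × 5 assays per
  gene) with true hits passing every filter and decoy classes each violating
  exactly one rule.
* ``gen_tirf_movie`` — TIRF time-lapses (150 frames at 6.67 fps) of Gaussian
  spots undergoing Brownian motion, docking, and two-frame fusion collapse,
  with photobleaching and Gaussian camera noise.
* ``gen_binding`` — saturation-binding curves and single-cycle sensorgrams
  forwarded through the models in :mod:`ldlscreen.binding`.

Every generator is a pure function of its spec and seed, and every generator
returns machine-readable ground truth next to the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binding import Injection, InjectionSchedule, Sensorgram, saturation_model, simulate_sensorgram
from .screen import PLATE_ROWS, Plate, Well

# ---------------------------------------------------------------------------
# screen


@dataclass
class ScreenSimSpec:
    """Stated world of the primary screen, at desk scale.

    2,000 genes over 384-well plates in triplicate stand in for the 18,119
    gene genome-wide screen; null intensities are log-normal (positive,
    right-skewed fluorescence); effects act multiplicatively, stated in
    plate-MAD units (for small sigma, an effect of m MADs multiplies the
    null median by ``1 + m*sigma``).
    """

    n_genes: int = 2000
    n_neg_controls: int = 16
    n_pos_controls: int = 16
    null_log_median: float = np.log(1000.0)  # a.u.
    null_log_sigma: float = 0.10
    control_cv: float = 0.05
    pos_control_effect: float = 0.8  # fractional reduction of uptake
    planted_effects: dict[str, float] = field(default_factory=dict)  # gene -> effect in MADs
    n_replicates: int = 3
    qc_fail_fraction: float = 0.01
    seed: int = 0

    @property
    def samples_per_plate(self) -> int:
        return 384 - self.n_neg_controls - self.n_pos_controls


def _well_labels() -> list[tuple[str, int]]:
    return [(r, c) for r in PLATE_ROWS for c in range(1, 25)]


def gen_screen(spec: ScreenSimSpec) -> tuple[list[Plate], pd.DataFrame]:
    """Generate all plates of a triplicate screen plus the planted-truth table.

    Returns ``(plates, truth)`` where ``truth`` has one row per gene with its
    planted effect in MAD units (0 for nulls).
    """
    for g, eff in spec.planted_effects.items():
        if eff == 0:
            raise ValueError(f"planted effect for {g} is 0; plant a real effect or omit")
    rng = np.random.default_rng(spec.seed)
    genes = [f"GENE{i:05d}" for i in range(spec.n_genes)]
    unknown = set(spec.planted_effects) - set(genes)
    if unknown:
        raise ValueError(f"planted genes not in the gene universe: {sorted(unknown)[:3]}")
    spp = spec.samples_per_plate
    n_plates = int(np.ceil(spec.n_genes / spp))
    labels = _well_labels()
    null_median = float(np.exp(spec.null_log_median))

    plates: list[Plate] = []
    for rep in range(1, spec.n_replicates + 1):
        for p in range(n_plates):
            plate_genes = genes[p * spp : (p + 1) * spp]
            wells: list[Well] = []
            li = iter(labels)
            pid = f"P{p + 1:03d}"
            for _ in range(spec.n_neg_controls):
                r, c = next(li)
                v = null_median * (1 + spec.control_cv * rng.standard_normal())
                wells.append(Well(pid, r, c, "neg_control", max(v, 0.0),
                                  cell_count=400, dead_fraction=0.02))
            for _ in range(spec.n_pos_controls):
                r, c = next(li)
                v = null_median * (1 - spec.pos_control_effect)
                v *= 1 + spec.control_cv * rng.standard_normal()
                wells.append(Well(pid, r, c, "pos_control", max(v, 0.0),
                                  cell_count=400, dead_fraction=0.02))
            for g in plate_genes:
                r, c = next(li)
                eff = spec.planted_effects.get(g, 0.0)
                mu = spec.null_log_median
                if eff:
                    factor = max(1.0 + eff * spec.null_log_sigma, 0.05)
                    mu = mu + np.log(factor)
                v = float(np.exp(mu + spec.null_log_sigma * rng.standard_normal()))
                if rng.random() < spec.qc_fail_fraction:
                    cell_count, dead = (int(rng.integers(10, 99)), 0.05)
                else:
                    cell_count, dead = (int(rng.integers(150, 600)), float(rng.uniform(0, 0.15)))
                wells.append(Well(pid, r, c, "sample", v, cell_count=cell_count,
                                  dead_fraction=dead, gene_id=g, sirna_id=f"si-{g}"))
            plates.append(Plate(pid, wells, replicate_id=rep))

    truth = pd.DataFrame(
        {
            "gene_id": genes,
            "effect_mads": [spec.planted_effects.get(g, 0.0) for g in genes],
        }
    )
    truth["is_hit"] = truth["effect_mads"] != 0.0
    return plates, truth


# ---------------------------------------------------------------------------
# follow-up / deconvolution


@dataclass
class FollowupSimSpec:
    """Composition of a deconvolution table: true hits plus decoy classes,
    each decoy violating exactly one cascade rule."""

    n_true: int = 10
    n_fail_dil: int = 100  # < 2 siRNAs active in the DiI confirmation
    n_tf_dirty: int = 20  # active but nonspecific (Tf-FITC >= 30%)
    n_ldlr_dep: int = 8  # >= 2 siRNAs with >= 2-fold LDLR high/low ratio
    n_huvec_fail: int = 2  # EA.hy926-only effect, not confirmed in HUVEC
    noise_sd: float = 3.0  # percent-inhibition replicate noise
    seed: int = 0

    @property
    def n_genes(self) -> int:
        return self.n_true + self.n_fail_dil + self.n_tf_dirty + self.n_ldlr_dep + self.n_huvec_fail


def _pair(rng, lo, hi, sd):
    base = rng.uniform(lo, hi)
    return base + rng.normal(0, sd), base + rng.normal(0, sd)


def gen_followup(spec: FollowupSimSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a long-format deconvolution table plus per-gene truth labels.

    True hits carry 3 DiI-active siRNAs (>= 50% both sets) with clean
    transferrin (< 30%), HUVEC confirmation and LDLR ratio ~ 1; each decoy
    class breaks exactly one rule.  Margins are wide relative to
    ``noise_sd`` so verdicts are deterministic given the seed.
    """
    rng = np.random.default_rng(spec.seed)
    rows: list[tuple] = []
    truth_rows: list[tuple] = []
    classes = (
        ["true_hit"] * spec.n_true
        + ["fail_dil"] * spec.n_fail_dil
        + ["tf_dirty"] * spec.n_tf_dirty
        + ["ldlr_dep"] * spec.n_ldlr_dep
        + ["huvec_fail"] * spec.n_huvec_fail
    )
    sd = spec.noise_sd

    for gi, cls in enumerate(classes):
        gene = f"CAND{gi:04d}"
        truth_rows.append((gene, cls, cls == "true_hit"))
        sirnas = [f"{gene}-s{j}" for j in range(1, 5)]
        # per-siRNA profiles: (dil_active, tf_dirty, ldlr_ratio, huvec_active)
        if cls == "fail_dil":
            active = [True] + [False] * 3  # one active siRNA only
        else:
            active = [True, True, True, False]
        for j, sirna in enumerate(sirnas):
            if active[j]:
                dil = _pair(rng, 60, 90, sd)
            else:
                dil = _pair(rng, 5, 35, sd)
            if cls == "tf_dirty" and j < 3:
                tf = _pair(rng, 45, 70, sd)
            else:
                tf = _pair(rng, 2, 18, sd)
            if cls == "huvec_fail":
                huvec = _pair(rng, 5, 30, sd)
            elif active[j]:
                huvec = _pair(rng, 60, 90, sd)
            else:
                huvec = _pair(rng, 5, 35, sd)
            base = rng.uniform(40, 70)
            if cls == "ldlr_dep" and j < 2:
                high = (base + rng.normal(0, sd), base + rng.normal(0, sd))
                low = tuple(v / 3.0 for v in high)  # 3-fold high/low difference
            else:
                high = (base + rng.normal(0, sd), base + rng.normal(0, sd))
                low = (base * rng.uniform(0.85, 1.15), base * rng.uniform(0.85, 1.15))
            for set_id, (d, t, h, hi_, lo_) in enumerate(
                zip(dil, tf, huvec, high, low), start=1
            ):
                rows.append((gene, sirna, "dil_ldl_eahy", set_id, d))
                rows.append((gene, sirna, "tf_fitc_eahy", set_id, t))
                rows.append((gene, sirna, "dil_ldl_huvec", set_id, h))
                rows.append((gene, sirna, "dil_ldl_ldlr_high", set_id, hi_))
                rows.append((gene, sirna, "dil_ldl_ldlr_low", set_id, lo_))

    records = pd.DataFrame(
        rows, columns=["gene_id", "sirna_id", "assay", "set_id", "percent_inhibition"]
    )
    truth = pd.DataFrame(truth_rows, columns=["gene_id", "class", "is_hit"])
    return records, truth


# ---------------------------------------------------------------------------
# TIRF movies


@dataclass
class TirfSimSpec:
    """Stated world of a TIRF transcytosis movie.

    150 frames at 6.67 fps; vesicles are Gaussian PSF spots over an offset
    background with Gaussian camera noise; a subset docks (near-zero
    diffusion) and fuses, collapsing to background over exactly 2 frames.
    """

    n_frames: int = 150
    frame_rate: float = 6.67  # s^-1
    shape: tuple[int, int] = (256, 256)
    n_vesicles: int = 45
    n_fusions: int = 30
    psf_sigma: float = 1.4  # px
    amplitude: float = 900.0  # peak above background, a.u.
    amplitude_cv: float = 0.2
    diffusion_step_sd: float = 0.8  # px / frame while mobile
    docked_step_sd: float = 0.05  # px / frame while docked
    min_dock_frames: int = 12
    max_dock_frames: int = 25
    #: intensity multipliers rendered at the fusion frame onwards; the
    #: vesicle is gone (local background) after the profile ends.  The
    #: default (0.5,) realises a linear two-frame collapse full -> half ->
    #: background, i.e. two equal consecutive intensity drops.
    collapse_fractions: tuple[float, ...] = (0.5,)
    bleach_rate: float = 0.005  # frame^-1 (slow photobleaching)
    background: float = 100.0  # camera offset
    noise_sd: float = 8.0
    #: minimum pairwise distance between initial vesicle positions (px);
    #: spots closer than ~2 PSF widths are unresolvable by any
    #: diffraction-limited detector, so distinct vesicles are planted at
    #: distinct sites.  Set 0 to disable.
    min_separation_px: float = 12.0
    seed: int = 0


def _render_spot(img: np.ndarray, r: float, c: float, amp: float, sigma: float) -> None:
    rad = int(np.ceil(4 * sigma))
    ri, ci = int(round(r)), int(round(c))
    r0, r1 = max(0, ri - rad), min(img.shape[0], ri + rad + 1)
    c0, c1 = max(0, ci - rad), min(img.shape[1], ci + rad + 1)
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    img[r0:r1, c0:c1] += amp * np.exp(-((rr - r) ** 2 + (cc - c) ** 2) / (2 * sigma**2))


def gen_tirf_movie(spec: TirfSimSpec) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a synthetic TIRF movie and its ground-truth fusion list.

    Fusing vesicles appear, wander briefly, dock (step s.d. ~0.05 px) for at
    least ``min_dock_frames``, then collapse to local background over two
    frames (full -> half -> gone by default; see ``collapse_fractions``).
    Non-fusing vesicles diffuse for the whole movie.  Returns ``(movie, truth)`` with one truth row per planted fusion
    (vesicle id, fusion frame, row, col).
    """
    if spec.n_fusions > spec.n_vesicles:
        raise ValueError("n_fusions cannot exceed n_vesicles")
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    margin = 10
    frames = np.zeros((spec.n_frames, h, w), dtype=float)
    truth_rows: list[tuple] = []

    # dart-throwing placement keeps distinct vesicles resolvable
    origins: list[tuple[float, float]] = []
    for _ in range(spec.n_vesicles):
        for _attempt in range(1000):
            r0 = rng.uniform(margin, h - margin)
            c0 = rng.uniform(margin, w - margin)
            if all(
                np.hypot(r0 - rr, c0 - cc) >= spec.min_separation_px for rr, cc in origins
            ):
                break
        else:
            raise ValueError(
                "could not place vesicles at the requested density/separation; "
                "enlarge the frame or lower n_vesicles"
            )
        origins.append((r0, c0))

    for v in range(spec.n_vesicles):
        fusing = v < spec.n_fusions
        amp = spec.amplitude * max(0.2, 1 + spec.amplitude_cv * rng.standard_normal())
        r, c = origins[v]
        if fusing:
            dock_len = int(rng.integers(spec.min_dock_frames, spec.max_dock_frames + 1))
            wander = int(rng.integers(3, 10))
            # fusion frame must leave room for wander + docking before it
            start = int(rng.integers(0, max(1, spec.n_frames - wander - dock_len - 8)))
            dock_start = start + wander
            fuse_frame = dock_start + dock_len
        else:
            start = int(rng.integers(0, spec.n_frames // 2))
            dock_start = fuse_frame = spec.n_frames + 10  # never docks

        # simulate the trajectory first so truth can record the fusion site
        traj: list[tuple[int, float, float]] = []
        for t in range(start, spec.n_frames):
            traj.append((t, r, c))
            if fusing and t == fuse_frame:
                truth_rows.append((v, fuse_frame, r, c))
            step_sd = spec.docked_step_sd if t >= dock_start else spec.diffusion_step_sd
            r = float(np.clip(r + rng.normal(0, step_sd), 1, h - 2))
            c = float(np.clip(c + rng.normal(0, step_sd), 1, w - 2))

        for t, rr, cc in traj:
            bleach = np.exp(-spec.bleach_rate * (t - start))
            if fusing and t >= fuse_frame:
                k = t - fuse_frame
                if k < len(spec.collapse_fractions):
                    a = spec.collapse_fractions[k] * amp * bleach
                else:
                    break  # vesicle gone
            else:
                a = amp * bleach
            _render_spot(frames[t], rr, cc, a, spec.psf_sigma)

    movie = frames + spec.background + rng.normal(0, spec.noise_sd, frames.shape)
    movie = np.clip(movie, 0, 65535).astype(np.uint16)
    truth = pd.DataFrame(truth_rows, columns=["vesicle_id", "fusion_frame", "row", "col"])
    return movie, truth


# ---------------------------------------------------------------------------
# binding


@dataclass
class BindingSimSpec:
    """Forward-model spec for binding data.

    ``model`` is ``"saturation"``, ``"kinetic"`` or ``"two_site"`` (two
    independent 1:1 species summed — the non-competitive scenario).
    """

    model: str = "saturation"
    k_d: float = 26.0  # saturation: µg ml^-1
    b_max: float = 67.0  # ng mg^-1
    nonspecific: float = 0.0
    concentrations: tuple = (2.0, 5.0, 10.0, 25.0, 50.0, 100.0)
    k_a: float = 5e4  # kinetic: (conc unit)^-1 s^-1
    k_d_rate: float = 0.01  # s^-1
    r_max: float = 100.0
    schedule: InjectionSchedule | None = None
    k_a2: float | None = None  # second independent site (two_site)
    k_d_rate2: float | None = None
    r_max2: float | None = None
    noise_sd: float = 0.0
    drift: float = 0.0
    seed: int = 0


ALK1_ECTO_UM = (0.19, 0.57, 1.7, 5.1, 15.3)  # µM analyte series
LDLR_ECTO_NM = (5.0, 14.0, 43.0, 129.0, 388.0)  # nM analyte series


def single_cycle_schedule(
    concentrations=ALK1_ECTO_UM,
    contact_s: float = 120.0,
    dissociation_s: float = 600.0,
) -> InjectionSchedule:
    """Single-cycle kinetics schedule: back-to-back injections of increasing
    concentration (no regeneration) followed by one dissociation phase."""
    injections = [
        Injection(c, i * contact_s, (i + 1) * contact_s)
        for i, c in enumerate(concentrations)
    ]
    return InjectionSchedule(
        injections=injections,
        dissociation_end=injections[-1].stop + dissociation_s,
        single_cycle=True,
    )


def gen_binding(spec: BindingSimSpec):
    """Forward-simulate binding data; returns ``(data, truth_dict)``.

    ``saturation`` → ``(DataFrame[concentration, bound], truth)`` with
    multiplicative noise of s.d. ``noise_sd`` (fractional);
    ``kinetic``/``two_site`` → ``(Sensorgram, truth)``.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.model == "saturation":
        conc = np.asarray(spec.concentrations, dtype=float)
        bound = saturation_model(conc, spec.b_max, spec.k_d, spec.nonspecific)
        if spec.noise_sd:
            bound = bound * (1 + rng.normal(0, spec.noise_sd, conc.shape))
        data = pd.DataFrame({"concentration": conc, "bound": bound})
        return data, {"k_d": spec.k_d, "b_max": spec.b_max, "nonspecific": spec.nonspecific}
    sched = spec.schedule or single_cycle_schedule()
    if spec.model == "kinetic":
        sg = simulate_sensorgram(
            spec.k_a, spec.k_d_rate, spec.r_max, sched,
            noise_sd=spec.noise_sd, drift=spec.drift, rng=rng,
        )
        return sg, {"k_a": spec.k_a, "k_d_rate": spec.k_d_rate, "r_max": spec.r_max,
                    "k_d": spec.k_d_rate / spec.k_a}
    if spec.model == "two_site":
        if None in (spec.k_a2, spec.k_d_rate2, spec.r_max2):
            raise ValueError("two_site model needs k_a2, k_d_rate2, r_max2")
        sg1 = simulate_sensorgram(spec.k_a, spec.k_d_rate, spec.r_max, sched)
        sg2 = simulate_sensorgram(spec.k_a2, spec.k_d_rate2, spec.r_max2, sched)
        resp = sg1.response + sg2.response
        if spec.noise_sd:
            resp = resp + rng.normal(0, spec.noise_sd, resp.shape)
        sg = Sensorgram(time=sg1.time, response=resp, schedule=sched)
        return sg, {"site1": {"k_a": spec.k_a, "k_d_rate": spec.k_d_rate, "r_max": spec.r_max},
                    "site2": {"k_a": spec.k_a2, "k_d_rate": spec.k_d_rate2,
                              "r_max": spec.r_max2}}
    raise ValueError(f"unknown model {spec.model!r}")
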