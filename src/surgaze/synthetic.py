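"""Synthetic study data: gaze streams, surfaces, masks, tear annotations.

No recordings were deposited with the study, so every downstream stage is
exercised on generated data whose statistical structure matches the
published group summaries. The generator is explicit about its model:

* A session is a sequence of *dwells* (ground-truth fixations) separated
  by instantaneous centroid jumps with 2-3 intermediate transit samples.
  Dwell durations follow a truncated log-normal on [80, 420] ms whose
  truncated mean equals the (participant-level) duration parameter;
  within-dwell jitter is isotropic truncated Gaussian noise. Jump
  amplitudes are log-normal with mean equal to the saccade parameter.
* Participant heterogeneity: the published group values are mean +/- SD
  across participants, so each session first draws its own duration,
  amplitude and HUD-share parameters from moment-matched truncated
  normals around the group values.
* Tracker confidence encodes event structure the way a pupil tracker
  does: dwell samples are high confidence (>= 0.85), transit and
  reorientation samples are degraded by motion (0.50-0.58 — below the 0.6
  analysis threshold, above the 0.5 blink floor), and blinks drop to
  ~0. After confidence filtering each dwell is a gap-delimited run, which
  is what lets a dispersion detector separate dwells whose spatial
  separation (< 0.3 degrees) is far below the 1.5 degree threshold.
* Area-of-interest structure: a session is divided into a handful of
  contiguous AOI blocks whose total time matches the session's AOI
  shares; gaze random-walks inside a work disk within the current
  surface, and between-block reorientations are emitted as low-confidence
  transit (they are head-scale shifts, not clean saccades).
* Blinks (full confidence dropouts of 100-300 ms) are inserted between
  dwells at the profile's rate.

Every generated quantity is logged to a ground-truth event list so
detector recovery can be tested oracle-style.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon

from .aoi import Surface
from .coverage import BLUE, MaskImage
from .events import GazeStream
from .geometry import ViewGeometry
from .profiles import ExpertiseProfile
from .rhexis import TearAnnotation
from .sampling import (
    lognormal_mu_for_truncated_mean,
    sample_truncated_lognormal,
    truncated_normal_mean_matched,
)

__all__ = [
    "GroundTruthEvent",
    "GroundTruthLog",
    "SessionRecord",
    "generate_surfaces",
    "generate_session",
    "generate_mask_image",
    "generate_tear_annotation",
    "generate_tear_outline",
    "generate_cohort",
    "derive_seed",
]

# dwell support = the detector's duration window
DWELL_LO, DWELL_HI = 0.080, 0.420
DWELL_LOGNORMAL_SHAPE = 0.45  # right-skew of within-session dwell durations
JUMP_LOGNORMAL_SHAPE = 0.40  # spread of within-session jump amplitudes
JITTER_CLIP_SD = 3.5  # truncate jitter so dwell dispersion stays classifiable
TRANSIT_CONF = (0.50, 0.58)  # motion-degraded tracker confidence
DWELL_CONF = (0.85, 1.0)
BLINK_CONF = (0.0, 0.05)
BLINK_DURATION = (0.10, 0.30)  # s
REORIENT_DURATION = (0.30, 0.50)  # s, between-AOI head-scale shifts
# Gaze work-disk radius inside an AOI, by visual sampling strategy: experts
# scan broadly across the operative field; novices cluster at the tool tip.
WORK_RADIUS = {"feed_forward": 4.0, "reactive": 1.5}  # degrees
# Feed-forward scanners periodically re-anchor their gaze cluster elsewhere
# in the work disk (a repositioning shift under tracking loss); reactive
# viewers stay locked to the tool tip.
RELOCATION_PERIOD = {"feed_forward": (2.0, 4.0), "reactive": None}  # s
RELOCATION_GAP = (0.15, 0.30)  # s of motion-degraded confidence


@dataclass(frozen=True)
class GroundTruthEvent:
    kind: str  # fixation | saccade | blink
    start: float
    end: float
    centroid_x: float = float("nan")
    centroid_y: float = float("nan")
    amplitude: float = float("nan")
    aoi: str = ""

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class GroundTruthLog:
    """Ordered ground-truth events for one generated session."""

    events: tuple[GroundTruthEvent, ...] = ()

    def of_kind(self, kind: str) -> list[GroundTruthEvent]:
        return [e for e in self.events if e.kind == kind]

    @property
    def fixations(self) -> list[GroundTruthEvent]:
        return self.of_kind("fixation")

    @property
    def saccades(self) -> list[GroundTruthEvent]:
        return self.of_kind("saccade")

    @property
    def blinks(self) -> list[GroundTruthEvent]:
        return self.of_kind("blink")


def generate_surfaces(geometry: ViewGeometry) -> list[Surface]:
    """Three disjoint labeled rectangles tiling the scene frame.

    The HUD occupies the left 60% of the frame (the display dominates the
    operating view); the instrument field is the upper-right block (the
    physical model under the scope), the peripheral view the remainder.
    """
    w, h = float(geometry.width_px), float(geometry.height_px)
    xsplit = round(w * 0.60)
    ysplit = round(h * 0.60)
    return [
        Surface("HUD", ((0.0, 0.0), (xsplit, 0.0), (xsplit, h), (0.0, h))),
        Surface(
            "instrument_field",
            ((xsplit, 0.0), (w, 0.0), (w, ysplit), (xsplit, ysplit)),
        ),
        Surface(
            "peripheral",
            ((xsplit, ysplit), (w, ysplit), (w, h), (xsplit, h)),
        ),
    ]


def derive_seed(base_seed: int, label: str, index: int) -> int:
    """Platform-stable per-session seed below 2**31."""
    return (base_seed * 1_000_003 + zlib.crc32(f"{label}/{index}".encode())) % (2**31)


def _work_disk(surface: Surface, geometry: ViewGeometry, margin_deg: float,
               max_radius: float):
    """(anchor_deg, radius_deg) of the gaze work disk inside a surface."""
    poly: Polygon = surface.polygon
    c = poly.centroid
    inner_px = poly.exterior.distance(c)
    radius = min(max_radius, inner_px * geometry.deg_per_px - margin_deg)
    if radius <= 0.2:
        raise ValueError(
            f"surface {surface.label!r} too small for a gaze work area"
        )
    ax, ay = geometry.px_to_deg(c.x, c.y)
    return (float(ax), float(ay)), float(radius)


def _session_parameters(profile: ExpertiseProfile, rng):
    """Participant-level parameter draws around the group values."""
    theta_dur = float(
        truncated_normal_mean_matched(
            profile.mean_fixation_duration,
            profile.fixation_duration_sd,
            DWELL_LO + 0.005,
            DWELL_HI - 0.005,
            rng,
        )
    )
    amp = profile.mean_saccade_amplitude
    theta_amp = float(
        truncated_normal_mean_matched(
            amp, profile.saccade_amplitude_sd, min(0.02, amp / 2), max(2.0, amp * 3), rng
        )
    )
    hud = profile.aoi_proportions.get("HUD", 0.0)
    if 0.0 < hud < 1.0 and profile.aoi_hud_sd > 0:
        theta_hud = float(
            truncated_normal_mean_matched(hud, profile.aoi_hud_sd, 0.02, 0.98, rng)
        )
    else:
        theta_hud = hud
    props = dict(profile.aoi_proportions)
    rest = sum(v for k, v in props.items() if k != "HUD")
    theta_props = {"HUD": theta_hud}
    for k, v in props.items():
        if k != "HUD":
            theta_props[k] = (1.0 - theta_hud) * (v / rest) if rest > 0 else 0.0
    return theta_dur, theta_amp, theta_props


def _block_schedule(theta_props: dict[str, float], duration: float, rng):
    """Contiguous (label, seconds) AOI blocks covering the session."""
    blocks: list[tuple[str, float]] = []
    for label in sorted(theta_props):
        t_total = theta_props[label] * duration
        if t_total <= 0:
            continue
        if t_total > 8.0:  # split long allocations into two visits
            u = rng.uniform(0.35, 0.65)
            blocks.extend([(label, t_total * u), (label, t_total * (1 - u))])
        else:
            blocks.append((label, t_total))
    if not blocks:
        raise ValueError("profile AOI proportions allocate no time")
    for _ in range(200):
        order = rng.permutation(len(blocks))
        seq = [blocks[i] for i in order]
        if all(seq[i][0] != seq[i + 1][0] for i in range(len(seq) - 1)):
            return seq
    return seq  # pragma: no cover - fallback for degenerate label sets


def generate_session(
    profile: ExpertiseProfile,
    geometry: ViewGeometry | None = None,
    surfaces: list[Surface] | None = None,
    duration: float | None = None,
    seed: int = 0,
) -> tuple[GazeStream, GroundTruthLog]:
    """Generate one session's gaze stream plus its ground-truth event log.

    ``duration=None`` derives a session length from the profile's expected
    fixation count. Identical (profile, seed) pairs reproduce identical
    streams bit for bit.
    """
    profile.validate()
    geometry = geometry or ViewGeometry()
    surfaces = surfaces if surfaces is not None else generate_surfaces(geometry)
    dt = 1.0 / geometry.nominal_rate
    if duration is None:
        duration = profile.fixation_count * (profile.mean_fixation_duration + 4 * dt)
    if not (duration > 0 and math.isfinite(duration)):
        raise ValueError(f"duration must be positive and finite, got {duration}")

    surf_by_label = {s.label: s for s in surfaces}
    needed = {k for k, v in profile.aoi_proportions.items() if v > 0}
    missing = needed - set(surf_by_label)
    if missing:
        raise ValueError(f"surfaces missing for AOI labels: {sorted(missing)}")

    rng = np.random.default_rng(seed)
    theta_dur, theta_amp, theta_props = _session_parameters(profile, rng)
    # solve the dwell-duration log-location once per session
    dwell_mu = lognormal_mu_for_truncated_mean(
        theta_dur, DWELL_LOGNORMAL_SHAPE, DWELL_LO, DWELL_HI
    )
    margin = JITTER_CLIP_SD * profile.noise_sd + 0.2
    max_radius = WORK_RADIUS[profile.strategy]
    disks = {
        lab: _work_disk(surf_by_label[lab], geometry, margin, max_radius)
        for lab in needed
    }
    # blink insertion probability per dwell cycle, solved so the expected
    # blink rate matches the profile despite blinks lengthening the cycle
    per_s = profile.blink_rate / 60.0
    cycle = theta_dur + 3.5 * dt
    mean_blink = float(np.mean(BLINK_DURATION))
    p_blink = max(0.0, min(0.95, per_s * cycle / max(1e-9, 1.0 - per_s * mean_blink)))

    n_total = int(round(duration / dt))
    k_min = int(math.ceil(DWELL_LO / dt))
    xs: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    cs: list[np.ndarray] = []
    events: list[GroundTruthEvent] = []
    i = 0  # global grid index; timestamps are i * dt

    def emit(x_arr, y_arr, c_arr):
        nonlocal i
        xs.append(np.asarray(x_arr, dtype=float))
        ys.append(np.asarray(y_arr, dtype=float))
        cs.append(np.asarray(c_arr, dtype=float))
        i += len(xs[-1])

    def emit_const(n, x, y, lo, hi):
        emit(np.full(n, x), np.full(n, y), rng.uniform(lo, hi, n))

    def jump_from(pos, anchor, radius, amp):
        for _ in range(200):
            phi = rng.uniform(0.0, 2.0 * math.pi)
            cand = (pos[0] + amp * math.cos(phi), pos[1] + amp * math.sin(phi))
            if math.hypot(cand[0] - anchor[0], cand[1] - anchor[1]) <= radius:
                return cand
        # step toward the anchor (always stays inside for amp <= radius)
        d = math.hypot(anchor[0] - pos[0], anchor[1] - pos[1]) or 1.0
        ux, uy = (anchor[0] - pos[0]) / d, (anchor[1] - pos[1]) / d
        return (pos[0] + amp * ux, pos[1] + amp * uy)

    pos = None
    schedule = _block_schedule(theta_props, duration, rng)
    block_start = 0
    for label, seconds in schedule:
        anchor, radius = disks[label]
        block_end = min(n_total, block_start + int(round(seconds / dt)))
        # enter the block: reorient from the previous position
        r0 = rng.uniform(0.0, 0.5 * radius)
        phi0 = rng.uniform(0.0, 2.0 * math.pi)
        target = (anchor[0] + r0 * math.cos(phi0), anchor[1] + r0 * math.sin(phi0))
        if pos is not None and i < block_end:
            m = int(round(rng.uniform(*REORIENT_DURATION) / dt))
            # short blocks keep at most a quarter for reorientation so that
            # near-minimal sessions still fit a dwell
            m = min(m, block_end - i, max(1, (block_end - i) // 4))
            if m > 0:
                fr = (np.arange(m) + 1) / (m + 1)
                emit(
                    pos[0] + fr * (target[0] - pos[0]),
                    pos[1] + fr * (target[1] - pos[1]),
                    rng.uniform(*TRANSIT_CONF, m),
                )
        pos = target
        prev_dwell_end = None
        reloc_cfg = RELOCATION_PERIOD[profile.strategy]
        next_reloc = (
            i * dt + rng.uniform(*reloc_cfg) if reloc_cfg is not None else math.inf
        )
        while i < block_end:
            if i * dt >= next_reloc and block_end - i > 3 * k_min:
                # re-anchor the gaze cluster elsewhere in the work disk
                m = int(round(rng.uniform(*RELOCATION_GAP) / dt))
                m = min(m, block_end - i)
                r_new = radius * math.sqrt(rng.uniform(0.0, 0.81))
                phi_new = rng.uniform(0.0, 2.0 * math.pi)
                new_pos = (
                    anchor[0] + r_new * math.cos(phi_new),
                    anchor[1] + r_new * math.sin(phi_new),
                )
                fr = (np.arange(m) + 1) / (m + 1)
                emit(
                    pos[0] + fr * (new_pos[0] - pos[0]),
                    pos[1] + fr * (new_pos[1] - pos[1]),
                    rng.uniform(*TRANSIT_CONF, m),
                )
                pos = new_pos
                prev_dwell_end = None  # repositioning is not a clean saccade
                next_reloc = i * dt + rng.uniform(*reloc_cfg)
                continue
            d_draw = float(
                sample_truncated_lognormal(
                    dwell_mu, DWELL_LOGNORMAL_SHAPE, DWELL_LO, DWELL_HI, rng
                )
            )
            k = int(round(d_draw / dt))
            if i + k >= block_end:  # dwell does not fit whole; try clipping
                k = block_end - 1 - i
                if k < k_min:
                    if block_end - i > 0:  # sub-threshold remainder: filler
                        emit_const(block_end - i, pos[0], pos[1], *TRANSIT_CONF)
                    break
            t0, t1 = i * dt, (i + k) * dt
            jit = rng.standard_normal((k + 1, 2)) * profile.noise_sd
            if profile.noise_sd > 0:
                lim = JITTER_CLIP_SD * profile.noise_sd
                np.clip(jit, -lim, lim, out=jit)
            emit(pos[0] + jit[:, 0], pos[1] + jit[:, 1], rng.uniform(*DWELL_CONF, k + 1))
            events.append(
                GroundTruthEvent(
                    "fixation", t0, t1,
                    centroid_x=pos[0], centroid_y=pos[1], aoi=label,
                )
            )
            if prev_dwell_end is not None:
                events.append(
                    GroundTruthEvent(
                        "saccade", prev_dwell_end, t0, amplitude=last_amp, aoi=label
                    )
                )
            prev_dwell_end = t1

            # transit to the next dwell position
            if i >= block_end:
                break
            amp = float(
                rng.lognormal(
                    math.log(theta_amp) - JUMP_LOGNORMAL_SHAPE**2 / 2.0,
                    JUMP_LOGNORMAL_SHAPE,
                )
            )
            amp = float(np.clip(amp, 0.01, 0.9 * radius))
            new = jump_from(pos, anchor, radius, amp)
            n_t = int(rng.integers(2, 4))
            n_t = min(n_t, block_end - i)
            if n_t > 0:
                fr = (np.arange(n_t) + 1) / (n_t + 1)
                emit(
                    pos[0] + fr * (new[0] - pos[0]),
                    pos[1] + fr * (new[1] - pos[1]),
                    rng.uniform(*TRANSIT_CONF, n_t),
                )
            pos = new
            last_amp = amp
            # occasional blink between dwells
            if rng.random() < p_blink and i < block_end:
                m = int(round(rng.uniform(*BLINK_DURATION) / dt))
                m = min(m, block_end - i - 1)
                if m >= 1:
                    b0, b1 = i * dt, (i + m) * dt
                    emit_const(m + 1, pos[0], pos[1], *BLINK_CONF)
                    events.append(GroundTruthEvent("blink", b0, b1))
                    prev_dwell_end = None  # blink interrupts the saccade pair
        block_start = block_end

    if i < n_total:  # trailing remainder of the requested duration
        p = pos if pos is not None else (
            sum(a for (a, _b), _r in disks.values()) / len(disks),
            sum(b for (_a, b), _r in disks.values()) / len(disks),
        )
        emit_const(n_total - i, p[0], p[1], *TRANSIT_CONF)

    n = i
    stream = GazeStream(
        t=np.arange(n) * dt,
        x=np.concatenate(xs) if xs else np.empty(0),
        y=np.concatenate(ys) if ys else np.empty(0),
        confidence=np.clip(np.concatenate(cs), 0.0, 1.0) if cs else np.empty(0),
        nominal_rate=geometry.nominal_rate,
    )
    events.sort(key=lambda e: (e.start, e.kind))
    return stream, GroundTruthLog(events=tuple(events))


def generate_mask_image(
    geometry: ViewGeometry,
    model_circle: tuple[tuple[float, float], float],
    background: tuple[int, int, int] = (30, 30, 30),
) -> MaskImage:
    """Baseline mask: the model-circle region carries the exact blue label."""
    (cx, cy), radius = model_circle
    if radius < 0:
        raise ValueError("model circle radius must be >= 0")
    w, h = geometry.width_px, geometry.height_px
    if not (radius <= cx <= w - radius and radius <= cy <= h - radius):
        raise ValueError("model circle must lie fully inside the frame")
    px = np.empty((h, w, 3), dtype=np.uint8)
    px[...] = background
    if radius > 0:
        from skimage.draw import disk as _disk

        rr, cc = _disk((cy, cx), radius, shape=(h, w))
        px[rr, cc] = BLUE
    return MaskImage(pixels=px)


def _rotate(v: tuple[float, float], deg: float) -> tuple[float, float]:
    a = math.radians(deg)
    return (
        v[0] * math.cos(a) - v[1] * math.sin(a),
        v[0] * math.sin(a) + v[1] * math.cos(a),
    )


def generate_tear_annotation(
    profile: ExpertiseProfile,
    seed: int = 0,
    center: tuple[float, float] = (640.0, 360.0),
    radius: float = 150.0,
) -> TearAnnotation:
    """One annotated capsulorhexis attempt drawn from the profile.

    The true tear-vector/forceps angle is a moment-matched truncated
    normal on [0, 180) degrees (directed convention); the tear path is a
    circular arc whose length over the travel-circle circumference matches
    the profile's diameter fraction; the initiation point sits on the
    circle at the profile's wound distance.
    """
    profile.validate()
    rng = np.random.default_rng(seed)
    if profile.tear_angle_sd > 0:
        lo = 0.0 if profile.tear_angle_mean > 0 else -1e-9
        angle = float(
            truncated_normal_mean_matched(
                profile.tear_angle_mean, profile.tear_angle_sd, lo, 180.0, rng
            )
        )
    else:
        angle = profile.tear_angle_mean
    frac = float(
        truncated_normal_mean_matched(
            profile.diameter_fraction_mean,
            profile.diameter_fraction_sd,
            0.02, 0.98, rng,
        )
    ) if profile.diameter_fraction_sd > 0 else profile.diameter_fraction_mean

    # wound point on the travel circle; forceps axis points inward from it
    phi_w = rng.uniform(0.0, 2.0 * math.pi)
    wound = (
        center[0] + radius * math.cos(phi_w),
        center[1] + radius * math.sin(phi_w),
    )
    u = _rotate((1.0, 0.0), rng.uniform(0.0, 360.0))  # forceps direction
    forceps_axis = (wound, (wound[0] + 1.2 * radius * u[0], wound[1] + 1.2 * radius * u[1]))
    sign = 1.0 if rng.random() < 0.5 else -1.0
    v = _rotate(u, sign * angle)

    # initiation point on the circle at the target wound distance
    d_target = float(
        truncated_normal_mean_matched(
            profile.initiation_distance_mean,
            profile.initiation_distance_sd,
            0.01, 1.95, rng,
        )
    ) if profile.initiation_distance_sd > 0 else profile.initiation_distance_mean
    psi = 2.0 * math.asin(min(1.0, d_target / 2.0))
    phi0 = phi_w + (1.0 if rng.random() < 0.5 else -1.0) * psi

    # tear path: an arc spanning frac of the circumference, from phi0
    span = frac * 2.0 * math.pi
    direction = 1.0 if rng.random() < 0.5 else -1.0
    phis = phi0 + direction * np.linspace(0.0, span, 128)
    path = tuple(
        (center[0] + radius * math.cos(p), center[1] + radius * math.sin(p))
        for p in phis
    )
    tear_tip = path[-1]
    tear_vector = (tear_tip, (tear_tip[0] + 0.5 * radius * v[0], tear_tip[1] + 0.5 * radius * v[1]))
    return TearAnnotation(
        forceps_axis=forceps_axis,
        tear_vector=tear_vector,
        travel_circle=(center, radius),
        tear_path=path,
        initiation_point=path[0],
        wound_point=wound,
        model_reference_length=2.0 * math.pi * radius,
    )


def generate_tear_outline(
    profile: ExpertiseProfile,
    seed: int = 0,
    center: tuple[float, float] = (640.0, 360.0),
    radius: float = 150.0,
    n_points: int = 256,
) -> tuple[tuple[float, float], ...]:
    """A closed tear outline whose regularity reflects surgical strategy.

    Feed-forward (expert) tears are nearly circular; reactive (novice)
    tears carry larger low-order radial perturbations, mirroring the
    irregular, tangentially pulled shapes seen in trainees.
    """
    rng = np.random.default_rng(seed)
    eps = 0.02 if profile.strategy == "feed_forward" else 0.12
    phis = np.linspace(0.0, 2.0 * math.pi, n_points, endpoint=False)
    r = np.full(n_points, float(radius))
    for harmonic in range(2, 6):
        a = rng.normal(0.0, eps * radius / harmonic)
        delta = rng.uniform(0.0, 2.0 * math.pi)
        r += a * np.cos(harmonic * phis + delta)
    pts = np.column_stack([center[0] + r * np.cos(phis), center[1] + r * np.sin(phis)])
    pts = np.vstack([pts, pts[0]])  # close explicitly
    return tuple(map(tuple, pts))


@dataclass(frozen=True)
class SessionRecord:
    """One generated cohort session with its provenance."""

    label: str
    replicate: int
    seed: int
    stream: GazeStream
    log: GroundTruthLog
    annotation: TearAnnotation


def generate_cohort(
    profiles: list[ExpertiseProfile],
    n_per_group: int,
    base_seed: int,
    geometry: ViewGeometry | None = None,
    surfaces: list[Surface] | None = None,
    duration: float = 300.0,
) -> tuple[list[SessionRecord], dict]:
    """n_per_group sessions per profile, with a reproducibility manifest.

    Per-session seeds derive stably from (base_seed, group label,
    replicate index); the manifest records every seed and parameter so the
    cohort can be regenerated exactly.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    labels = [p.label for p in profiles]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate profile labels: {sorted(labels)}")
    geometry = geometry or ViewGeometry()
    surfaces = surfaces if surfaces is not None else generate_surfaces(geometry)

    records: list[SessionRecord] = []
    manifest: dict = {
        "base_seed": base_seed,
        "n_per_group": n_per_group,
        "duration_s": duration,
        "geometry": {
            "width_px": geometry.width_px,
            "height_px": geometry.height_px,
            "diagonal_fov": geometry.diagonal_fov,
            "nominal_rate": geometry.nominal_rate,
        },
        "sessions": [],
    }
    for p in profiles:
        for r in range(n_per_group):
            seed = derive_seed(base_seed, p.label, r)
            stream, log = generate_session(p, geometry, surfaces, duration, seed)
            ann = generate_tear_annotation(p, seed=derive_seed(base_seed, p.label + "/tear", r))
            records.append(SessionRecord(p.label, r, seed, stream, log, ann))
            manifest["sessions"].append(
                {
                    "label": p.label,
                    "replicate": r,
                    "seed": seed,
                    "n_samples": len(stream),
                    "profile": {
                        "mean_fixation_duration": p.mean_fixation_duration,
                        "mean_saccade_amplitude": p.mean_saccade_amplitude,
                        "aoi_proportions": dict(p.aoi_proportions),
                        "tear_angle_mean": p.tear_angle_mean,
                        "tear_angle_sd": p.tear_angle_sd,
                        "diameter_fraction_mean": p.diameter_fraction_mean,
                        "blink_rate": p.blink_rate,
                        "noise_sd": p.noise_sd,
                        "strategy": p.strategy,
                    },
                }
            )
    return records, manifest
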