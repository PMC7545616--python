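"""Synthetic data emulating the two fibroblast Ca2+ assays and variant tables.

The generators reproduce the *statistical structure* the downstream analyses
assume, not cell physiology:

* :func:`simulate_evoked_trace` — single-cell Fluo-4 fluorescence under the
  12-minute five-phase perfusion protocol (Ca2+ HBSS, 0-Ca2+, ATP, 0-Ca2+,
  Ca2+ re-addition for store-operated entry). The agonist-evoked transient is
  a minimal separable rise/decay model
  ``a * (1 - exp(-s/tau_rise)) * exp(-s/tau_decay)`` whose closed form makes
  analytic oracle checks possible.
* :func:`simulate_image_stack` — a multi-page image whose per-ROI mean pixel
  value reproduces a given trace, for round-trip testing of ROI extraction.
* :func:`simulate_plate_traces` — 96-well Fura-2 two-channel (340/380 nm)
  series under the EGTA-then-stimulus plate protocol; F340 rises and F380
  falls with Ca2+ so that the baseline-normalized ratio follows a target
  transient independent of per-well gain.
* :func:`simulate_variant_table` — annotated variant tables in which every
  background record violates at least one filter criterion and spike-in
  records are inserted verbatim.

Genotype-dependent effects enter through :class:`GroupEffect` (amplitude
multiplier, latency shift, rise-time multiplier), mirroring the qualitative
patient/knockdown phenotypes: reduced AUC, increased time to peak.

Every ``simulate_*`` function is deterministic given its ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    LayoutError,
    ParameterError,
    Phase,
    PhaseSchedule,
    ScheduleError,
    Trace,
    WellTrace,
)

__all__ = [
    "CellParams",
    "GroupEffect",
    "RoiSpec",
    "RoiLayout",
    "PlateParams",
    "VariantRecord",
    "make_default_schedules",
    "transient",
    "transient_peak",
    "transient_time_to_peak",
    "simulate_evoked_trace",
    "simulate_evoked_experiment",
    "simulate_image_stack",
    "simulate_plate_traces",
    "plate_target_ratio",
    "simulate_variant_table",
    "index_family_variant",
    "de_novo_variant",
    "DEFAULT_SHARED_SAMPLES",
    "DEFAULT_TRIO",
]

AGONIST_PHASE = "atp"
SOCE_PHASE = "ca_readdition"
BASELINE_PHASE = "zero_ca"
STIMULUS_PHASE = "stimulus"


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellParams:
    """Per-cell generative parameters for the evoked (Fluo-4) assay.

    Defaults describe a healthy fibroblast responding to 80 umol/L ATP:
    resting fluorescence ``baseline_f0`` (arbitrary camera units), peak
    dF/F0 ``amplitude_a`` of ~1.5, a couple of seconds of response latency,
    fast rise (~3 s) and slower decay (~20 s), mild photobleaching drift and
    Gaussian read noise of ~2% of baseline.
    """

    baseline_f0: float = 100.0
    amplitude_a: float = 1.5
    latency_s: float = 2.0
    tau_rise_s: float = 3.0
    tau_decay_s: float = 20.0
    drift_per_s: float = -1e-4
    noise_sd: float = 2.0
    soce_amplitude: float = 0.3

    def __post_init__(self) -> None:
        if self.baseline_f0 <= 0:
            raise ParameterError("baseline_f0 must be positive")
        if self.tau_rise_s <= 0:
            raise ParameterError("tau_rise_s must be positive")
        if self.tau_decay_s <= self.tau_rise_s:
            raise ParameterError("tau_decay_s must exceed tau_rise_s")
        if self.amplitude_a < 0:
            raise ParameterError("amplitude_a must be non-negative")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be non-negative")


@dataclass(frozen=True)
class GroupEffect:
    """Genotype-dependent modulation of the evoked transient.

    A control group uses multiplier 1 and shift 0. Patient-like or
    knockdown-like groups scale the amplitude down and/or delay the response.
    """

    label: str = "control"
    amplitude_multiplier: float = 1.0
    latency_shift_s: float = 0.0
    tau_rise_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.amplitude_multiplier < 0:
            raise ParameterError("amplitude_multiplier must be >= 0")
        if self.tau_rise_multiplier <= 0:
            raise ParameterError("tau_rise_multiplier must be positive")


CONTROL_EFFECT = GroupEffect()


# ---------------------------------------------------------------------------
# Schedules
# ---------------------------------------------------------------------------

def make_default_schedules() -> tuple[PhaseSchedule, PhaseSchedule]:
    """Default perfusion schedules of the two assays.

    Returns
    -------
    evoked, plate:
        The 12-minute single-cell protocol (3 min Ca2+ HBSS, 3 min 0-Ca2+,
        2 min ATP, 2 min 0-Ca2+, 2 min Ca2+ re-addition; 1 s frames) and the
        plate protocol (30 s rest, EGTA at 30 s, stimulus at 90 s monitored
        for 6 min; 5 s sampling).
    """
    evoked = PhaseSchedule(
        phases=(
            Phase("ca_hbss", 0.0, 180.0),
            Phase(BASELINE_PHASE, 180.0, 360.0),
            Phase(AGONIST_PHASE, 360.0, 480.0),
            Phase("zero_ca_post", 480.0, 600.0),
            Phase(SOCE_PHASE, 600.0, 720.0),
        ),
        frame_interval_s=1.0,
    )
    plate = PhaseSchedule(
        phases=(
            Phase("rest", 0.0, 30.0),
            Phase("egta", 30.0, 90.0),
            Phase(STIMULUS_PHASE, 90.0, 450.0),
        ),
        frame_interval_s=5.0,
    )
    return evoked, plate


# ---------------------------------------------------------------------------
# Transient model
# ---------------------------------------------------------------------------

def transient(
    t: np.ndarray, t0: float, amplitude: float, tau_rise_s: float, tau_decay_s: float
) -> np.ndarray:
    """Separable rise/decay transient, zero before onset ``t0``.

    ``f(s) = amplitude * (1 - exp(-s/tau_rise)) * exp(-s/tau_decay)`` for
    ``s = t - t0 >= 0``. Note the peak value is below ``amplitude``; use
    :func:`transient_peak` for the analytic maximum.
    """
    t = np.asarray(t, dtype=float)
    s = t - t0
    out = np.zeros_like(s)
    pos = s >= 0
    sp = s[pos]
    out[pos] = (
        amplitude
        * (1.0 - np.exp(-sp / tau_rise_s))
        * np.exp(-sp / tau_decay_s)
    )
    return out


def transient_time_to_peak(tau_rise_s: float, tau_decay_s: float) -> float:
    """Analytic time from onset to the transient maximum."""
    return tau_rise_s * np.log1p(tau_decay_s / tau_rise_s)

def transient_peak(amplitude: float, tau_rise_s: float, tau_decay_s: float) -> float:
    """Analytic maximum of :func:`transient`."""
    s_star = transient_time_to_peak(tau_rise_s, tau_decay_s)
    return float(
        amplitude
        * (1.0 - np.exp(-s_star / tau_rise_s))
        * np.exp(-s_star / tau_decay_s)
    )


# ---------------------------------------------------------------------------
# Evoked single-cell traces
# ---------------------------------------------------------------------------

def simulate_evoked_trace(
    schedule: PhaseSchedule,
    params: CellParams = CellParams(),
    effect: GroupEffect = CONTROL_EFFECT,
    seed: int = 0,
    cell_id: str = "cell",
) -> Trace:
    """Simulate one cell's raw Fluo-4 fluorescence under ``schedule``.

    Raw fluorescence is
    ``F(t) = F0 * (1 + drift_per_s * t + transient(t) + soce(t)) + noise``
    with the agonist transient starting ``latency_s + latency_shift_s``
    after the ATP phase onset and the store-operated-entry transient
    confined to the Ca2+ re-addition phase.
    """
    agonist = schedule.phase(AGONIST_PHASE)
    t = schedule.times()

    t0 = agonist.start_s + params.latency_s + effect.latency_shift_s
    dff = transient(
        t,
        t0,
        params.amplitude_a * effect.amplitude_multiplier,
        params.tau_rise_s * effect.tau_rise_multiplier,
        params.tau_decay_s,
    )

    try:
        soce = schedule.phase(SOCE_PHASE)
    except ScheduleError:
        soce = None
    if soce is not None and params.soce_amplitude > 0:
        s = transient(
            t,
            soce.start_s + params.latency_s,
            params.soce_amplitude,
            params.tau_rise_s,
            params.tau_decay_s,
        )
        s[t >= soce.end_s] = 0.0
        dff = dff + s

    rng = np.random.default_rng(seed)
    values = params.baseline_f0 * (1.0 + params.drift_per_s * t + dff)
    if params.noise_sd > 0:
        values = values + rng.normal(0.0, params.noise_sd, size=t.shape)
    return Trace(
        id=cell_id,
        time_s=t,
        values=values,
        group=effect.label,
        phase_labels=schedule.labels_at(t),
    )


def simulate_evoked_experiment(
    schedule: PhaseSchedule,
    effect: GroupEffect,
    n_coverslips: int,
    cells_per_coverslip: int,
    seed: int = 0,
    base_params: CellParams = CellParams(),
    cell_cv: float = 0.15,
    coverslip_cv: float = 0.10,
    latency_jitter_s: float = 2.0,
) -> tuple[list[Trace], dict[str, str]]:
    """Simulate a multi-coverslip experiment for one genotype group.

    Biological variability enters at two levels: a lognormal per-coverslip
    amplitude factor (CV ``coverslip_cv``) shared by its cells, and lognormal
    per-cell variation (CV ``cell_cv``) of amplitude and baseline plus a
    truncated-normal latency jitter.

    Returns the traces and the cell-id -> coverslip-id map used for
    per-coverslip aggregation.
    """
    rng = np.random.default_rng(seed)
    traces: list[Trace] = []
    grouping: dict[str, str] = {}
    sig_cs = np.sqrt(np.log1p(coverslip_cv**2))
    sig_cell = np.sqrt(np.log1p(cell_cv**2))
    for cs in range(n_coverslips):
        cs_id = f"{effect.label}_cs{cs:02d}"
        cs_factor = rng.lognormal(-0.5 * sig_cs**2, sig_cs)
        for c in range(cells_per_coverslip):
            cell_id = f"{cs_id}_cell{c:02d}"
            amp = base_params.amplitude_a * cs_factor * rng.lognormal(
                -0.5 * sig_cell**2, sig_cell
            )
            f0 = base_params.baseline_f0 * rng.lognormal(
                -0.5 * sig_cell**2, sig_cell
            )
            lat = max(
                0.0, base_params.latency_s + rng.normal(0.0, latency_jitter_s)
            )
            params = CellParams(
                baseline_f0=f0,
                amplitude_a=amp,
                latency_s=lat,
                tau_rise_s=base_params.tau_rise_s,
                tau_decay_s=base_params.tau_decay_s,
                drift_per_s=base_params.drift_per_s,
                noise_sd=base_params.noise_sd,
                soce_amplitude=base_params.soce_amplitude,
            )
            cell_seed = int(rng.integers(0, 2**31 - 1))
            traces.append(
                simulate_evoked_trace(
                    schedule, params, effect, seed=cell_seed, cell_id=cell_id
                )
            )
            grouping[cell_id] = cs_id
    return traces, grouping


# ---------------------------------------------------------------------------
# Image stacks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RoiSpec:
    """Rectangular ROI: ``label`` over rows [y0, y0+height) x cols [x0, x0+width)."""

    label: int
    y0: int
    x0: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.label <= 0:
            raise LayoutError("ROI labels must be positive integers")
        if self.height <= 0 or self.width <= 0:
            raise LayoutError("ROI must have positive extent")


@dataclass(frozen=True)
class RoiLayout:
    """Frame geometry plus non-overlapping in-bounds ROIs."""

    frame_shape: tuple[int, int]
    rois: tuple[RoiSpec, ...]
    background: float = 10.0

    def __post_init__(self) -> None:
        h, w = self.frame_shape
        labels = [r.label for r in self.rois]
        if len(set(labels)) != len(labels):
            raise LayoutError("ROI labels must be distinct")
        occupied = np.zeros(self.frame_shape, dtype=bool)
        for r in self.rois:
            if r.y0 < 0 or r.x0 < 0 or r.y0 + r.height > h or r.x0 + r.width > w:
                raise LayoutError(
                    f"ROI {r.label} extends outside the {h}x{w} frame"
                )
            block = occupied[r.y0 : r.y0 + r.height, r.x0 : r.x0 + r.width]
            if block.any():
                raise LayoutError(f"ROI {r.label} overlaps another ROI")
            block[:] = True

    def label_image(self) -> np.ndarray:
        mask = np.zeros(self.frame_shape, dtype=np.int32)
        for r in self.rois:
            mask[r.y0 : r.y0 + r.height, r.x0 : r.x0 + r.width] = r.label
        return mask


def simulate_image_stack(
    layout: RoiLayout,
    traces: Sequence[Trace],
    seed: int = 0,
    pixel_noise_sd: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Render traces into a multi-page image stack plus integer label mask.

    Each ROI's pixels carry its trace value at every frame (plus optional
    i.i.d. Gaussian pixel noise); background pixels sit at a fixed low level.
    With ``pixel_noise_sd == 0`` the per-ROI mean at each frame recovers the
    input trace to floating-point rounding.
    """
    if len(traces) != len(layout.rois):
        raise LayoutError(
            f"{len(layout.rois)} ROIs but {len(traces)} traces supplied"
        )
    n_frames = traces[0].values.size
    for tr in traces:
        if tr.values.size != n_frames:
            raise LayoutError("all traces must have the same length")

    mask = layout.label_image()
    stack = np.full(
        (n_frames, *layout.frame_shape), layout.background, dtype=float
    )
    for roi, tr in zip(layout.rois, traces):
        stack[:, roi.y0 : roi.y0 + roi.height, roi.x0 : roi.x0 + roi.width] = (
            tr.values[:, None, None]
        )
    if pixel_noise_sd > 0:
        rng = np.random.default_rng(seed)
        stack = stack + rng.normal(0.0, pixel_noise_sd, size=stack.shape)
    return stack, mask


# ---------------------------------------------------------------------------
# Plate-reader wells
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlateParams:
    """Generative parameters for one Fura-2 plate well.

    ``f340_rest``/``f380_rest`` set the resting channel intensities (their
    quotient is the resting ratio, ~0.8 for Fura-2 at low Ca2+);
    ``amplitude`` is the peak of the baseline-normalized ratio transient at
    multiplier 1.
    """

    f340_rest: float = 800.0
    f380_rest: float = 1000.0
    amplitude: float = 1.0
    latency_s: float = 5.0
    tau_rise_s: float = 10.0
    tau_decay_s: float = 60.0
    noise_sd: float = 0.0
    well_cv: float = 0.10


def plate_target_ratio(
    schedule: PhaseSchedule,
    effect: GroupEffect = CONTROL_EFFECT,
    params: PlateParams = PlateParams(),
) -> np.ndarray:
    """Noise-free baseline-normalized target ratio curve ``g(t)``.

    ``g(t) = 1 + A * m * transient(t - t_stim - latency)`` where ``t_stim``
    is the stimulus-phase onset. The EGTA regime makes this release-only:
    nothing happens outside the stimulus transient.
    """
    stim = schedule.phase(STIMULUS_PHASE)
    t = schedule.times()
    t0 = stim.start_s + params.latency_s + effect.latency_shift_s
    return 1.0 + transient(
        t,
        t0,
        params.amplitude * effect.amplitude_multiplier,
        params.tau_rise_s * effect.tau_rise_multiplier,
        params.tau_decay_s,
    )


def simulate_plate_traces(
    schedule: PhaseSchedule,
    effects: Sequence[GroupEffect],
    wells_per_group: int = 5,
    seed: int = 0,
    stimulus: str = "bradykinin",
    params: PlateParams = PlateParams(),
) -> list[WellTrace]:
    """Simulate two-channel Fura-2 wells for each group.

    The channels move oppositely with Ca2+ — ``F340 = F340_rest * sqrt(g)``,
    ``F380 = F380_rest / sqrt(g)`` — so their ratio is ``R_rest * g(t)`` and
    the baseline-normalized ratio recovers the target curve ``g`` exactly in
    the noise-free case. A per-well lognormal gain (CV ``well_cv``) scales
    both channels identically, which downstream metrics must cancel.
    """
    if wells_per_group < 1:
        raise ParameterError("wells_per_group must be >= 1")
    rng = np.random.default_rng(seed)
    wells: list[WellTrace] = []
    sig = np.sqrt(np.log1p(params.well_cv**2)) if params.well_cv > 0 else 0.0
    for effect in effects:
        for w in range(wells_per_group):
            g = plate_target_ratio(schedule, effect, params)
            gain = rng.lognormal(-0.5 * sig**2, sig) if sig > 0 else 1.0
            f340 = params.f340_rest * gain * np.sqrt(g)
            f380 = params.f380_rest * gain / np.sqrt(g)
            if params.noise_sd > 0:
                f340 = f340 + rng.normal(0, params.noise_sd, size=g.shape)
                f380 = f380 + rng.normal(0, params.noise_sd, size=g.shape)
                f340 = np.maximum(f340, 1e-6)
                f380 = np.maximum(f380, 1e-6)
            wells.append(
                WellTrace(
                    well_id=f"{effect.label}_w{w:02d}",
                    time_s=schedule.times(),
                    f340=f340,
                    f380=f380,
                    group=effect.label,
                    stimulus=stimulus,
                )
            )
    return wells


# ---------------------------------------------------------------------------
# Variant tables
# ---------------------------------------------------------------------------

DEFAULT_SHARED_SAMPLES = ("P1", "P3")
DEFAULT_TRIO = ("P5", "father", "mother")

_CONSEQUENCES_NONSYN = (
    "missense",
    "stop_gain",
    "frameshift",
    "splice_site",
)


@dataclass(frozen=True)
class VariantRecord:
    """One annotated variant with per-sample genotypes.

    ``pop_freq`` is the allele frequency in a named reference subpopulation
    (``None`` = not observed); ``cadd`` the scaled deleteriousness score
    (``None`` = unscored). Genotypes use VCF diploid strings.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    consequence: str
    in_dbsnp: bool
    genotypes: Mapping[str, str]
    pop_freq: float | None = None
    cadd: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ParameterError("pos must be >= 1 (1-based)")
        if self.ref == self.alt:
            raise ParameterError("ref and alt must differ")
        if self.pop_freq is not None and not 0.0 <= self.pop_freq <= 1.0:
            raise ParameterError("pop_freq must lie in [0, 1]")
        if "," in self.alt:
            raise ParameterError(
                "multi-allelic records must be split into one ALT per row"
            )

    def to_row(self) -> dict:
        row = {
            "chrom": self.chrom,
            "pos": self.pos,
            "ref": self.ref,
            "alt": self.alt,
            "consequence": self.consequence,
            "in_dbsnp": self.in_dbsnp,
            "pop_freq": np.nan if self.pop_freq is None else self.pop_freq,
            "cadd": np.nan if self.cadd is None else self.cadd,
        }
        for sample, gt in self.genotypes.items():
            row[f"gt_{sample}"] = gt
        return row


def index_family_variant(
    samples: Sequence[str] = DEFAULT_SHARED_SAMPLES, cadd: float = 25.9
) -> VariantRecord:
    """Synthetic stand-in for the dominant-family ITPR3 index variant.

    Mirrors the filter profile of c.1843G>A (p.Val615Met): heterozygous in
    both affected exomes, missense, absent from dbSNP and the reference
    subpopulation, CADD well above 15. Genomic coordinates are illustrative.
    """
    return VariantRecord(
        chrom="6",
        pos=33646733,
        ref="G",
        alt="A",
        consequence="missense",
        in_dbsnp=False,
        pop_freq=None,
        cadd=cadd,
        genotypes={s: "0/1" for s in samples},
    )


def de_novo_variant(trio: Sequence[str] = DEFAULT_TRIO) -> VariantRecord:
    """Synthetic stand-in for the trio's de novo ITPR3 variant.

    Mirrors c.7570C>T (p.Arg2524Cys): heterozygous in the proband, absent
    from both parents and from population databases, CADD 32. Genomic
    coordinates are illustrative.
    """
    proband, father, mother = trio
    return VariantRecord(
        chrom="6",
        pos=33664289,
        ref="C",
        alt="T",
        consequence="missense",
        in_dbsnp=False,
        pop_freq=None,
        cadd=32.0,
        genotypes={proband: "0/1", father: "0/0", mother: "0/0"},
    )


def simulate_variant_table(
    n_background: int,
    spike_in: Sequence[VariantRecord] = (),
    seed: int = 0,
    samples: Sequence[str] = DEFAULT_SHARED_SAMPLES,
    max_pop_freq: float = 1e-5,
    min_cadd: float = 15.0,
) -> pd.DataFrame:
    """Background variants that each fail >= 1 dominant-filter criterion,
    plus ``spike_in`` records inserted verbatim.

    Each background record is assigned one violation drawn uniformly from:
    excluded consequence class, dbSNP membership, population frequency above
    ``max_pop_freq``, CADD below ``min_cadd`` (or unscored), or genotype not
    shared by all ``samples``. Rows are shuffled deterministically; the
    filter must be order-invariant anyway.
    """
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    violations = ("consequence", "dbsnp", "frequency", "cadd", "not_shared")
    for i in range(n_background):
        kind = violations[rng.integers(len(violations))]
        consequence = str(rng.choice(_CONSEQUENCES_NONSYN))
        in_dbsnp = False
        pop_freq: float | None = None
        cadd: float | None = float(rng.uniform(15.0, 40.0))
        genotypes = {s: "0/1" for s in samples}
        if kind == "consequence":
            consequence = str(
                rng.choice(["synonymous", "inframe_insertion", "inframe_deletion"])
            )
        elif kind == "dbsnp":
            in_dbsnp = True
        elif kind == "frequency":
            pop_freq = float(rng.uniform(max_pop_freq * 10, 0.05))
        elif kind == "cadd":
            cadd = None if rng.random() < 0.3 else float(rng.uniform(0.0, min_cadd - 0.01))
        else:  # not shared by every affected sample
            missing = str(rng.choice(list(samples)))
            genotypes[missing] = str(rng.choice(["0/0", "./."]))
        ref = str(rng.choice(["A", "C", "G", "T"]))
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        rec = VariantRecord(
            chrom=str(rng.choice(["1", "2", "7", "11", "17", "X"])),
            pos=int(rng.integers(10_000, 50_000_000)),
            ref=ref,
            alt=alt,
            consequence=consequence,
            in_dbsnp=in_dbsnp,
            pop_freq=pop_freq,
            cadd=cadd,
            genotypes=genotypes,
        )
        rows.append(rec.to_row())
    rows.extend(rec.to_row() for rec in spike_in)
    table = pd.DataFrame(rows)
    if len(table):
        order = rng.permutation(len(table))
        table = table.iloc[order].reset_index(drop=True)
    return table
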