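"""Method-comparison statistics for paired fat-mass measurements.

Reproduces the validation design in which the image-based fat mass of
each animal is compared against an independent whole-body reference
readout (an EchoMRI-style analyser): squared Pearson correlation,
ordinary least-squares slope/intercept of reference on pipeline, and the
mean relative difference, plus a cohort-level simulation experiment that
runs the whole chain on synthetic phantoms.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from . import fatwater, phantom

__all__ = [
    "PairedMeasurements",
    "AgreementReport",
    "pearson_r2",
    "agreement_report",
    "cohort_validation",
    "cohort_correlation_experiment",
]


@dataclass(frozen=True)
class PairedMeasurements:
    """Per-subject measurement pairs (same quantity, same units, two
    methods)."""

    a: np.ndarray
    b: np.ndarray
    ids: tuple = ()

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=float)
        b = np.asarray(self.b, dtype=float)
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)
        if a.ndim != 1 or a.shape != b.shape:
            raise ValueError("paired measurements must be 1-D arrays of equal length")
        if len(a) < 2:
            raise ValueError("need at least 2 pairs")
        if not (np.isfinite(a).all() and np.isfinite(b).all()):
            raise ValueError("measurements must be finite")
        if self.ids and len(self.ids) != len(a):
            raise ValueError("ids length does not match measurements")

    def __len__(self) -> int:
        return len(self.a)


def pearson_r2(pairs: PairedMeasurements) -> float:
    """Squared Pearson product-moment correlation of the two methods."""
    if len(pairs) < 3:
        raise ValueError("correlation needs at least 3 pairs")
    if np.var(pairs.a) == 0 or np.var(pairs.b) == 0:
        raise ValueError("correlation undefined: a coordinate has zero variance")
    r = stats.pearsonr(pairs.a, pairs.b).statistic
    return float(r**2)


@dataclass(frozen=True)
class AgreementReport:
    """Effect-size summary of a two-method comparison."""

    n: int
    r_squared: float
    p_value: float
    slope: float
    intercept: float
    mean_relative_difference: float


def agreement_report(pairs: PairedMeasurements) -> AgreementReport:
    """Correlation, least-squares line of method B on method A, and the
    mean relative difference ``mean((B - A) / A)`` over subjects with
    ``A > 0``."""
    r2 = pearson_r2(pairs)
    res = stats.pearsonr(pairs.a, pairs.b)
    slope, intercept = np.polyfit(pairs.a, pairs.b, 1)
    positive = pairs.a > 0
    if not positive.any():
        raise ValueError("mean relative difference needs at least one A > 0")
    mrd = float(np.mean((pairs.b[positive] - pairs.a[positive]) / pairs.a[positive]))
    return AgreementReport(
        n=len(pairs),
        r_squared=r2,
        p_value=float(res.pvalue),
        slope=float(slope),
        intercept=float(intercept),
        mean_relative_difference=mrd,
    )


def cohort_validation(
    cohort,
    density: float = fatwater.DEFAULT_FAT_DENSITY,
    k: float = fatwater.DEFAULT_FOREGROUND_K,
):
    """Quantify every phantom pair of a simulated cohort and compare
    against the reference readouts.

    ``cohort`` is a list of ``(fat_stack, water_stack, truth, reference)``
    tuples as produced by :func:`fishfat.phantom.make_cohort`.  Returns
    ``(pairs, report)`` where method A is the pipeline fat mass and
    method B the reference readout.
    """
    pipeline, reference = [], []
    for fat_stack, water_stack, _truth, ref in cohort:
        q = fatwater.quantify_pair(fat_stack, water_stack, density=density, k=k)
        pipeline.append(q.fat_mass_mg)
        reference.append(ref)
    pairs = PairedMeasurements(np.array(pipeline), np.array(reference))
    return pairs, agreement_report(pairs)


def cohort_correlation_experiment(
    n_seeds: int = 100,
    n_phantoms: int = 8,
    mass_range_mg: tuple[float, float] = phantom.DEFAULT_COHORT_MASS_RANGE,
    peak_snr: float = 20.0,
    reference_cv: float = 0.02,
    base_spec: phantom.PhantomSpec | None = None,
    seed: int = 0,
    k: float = fatwater.DEFAULT_FOREGROUND_K,
) -> np.ndarray:
    """Repeat the cohort validation over many noise realisations.

    The geometric cohort design (phantom shapes and ground-truth masses)
    is built once; each seed redraws the acquisition noise at the
    requested peak signal-to-noise ratio and the reference readout, runs
    the full quantification chain and records the squared Pearson
    correlation between pipeline and reference fat masses.  Returns the
    per-seed R^2 values.
    """
    design = phantom.design_cohort(n_phantoms, mass_range_mg, base_spec)
    # one sigma per animal so every acquisition has the same peak SNR
    sigmas = [
        phantom.sigma_for_peak_snr(spec, peak_snr, fat, water)
        for spec, fat, water, _ in design
    ]
    root = np.random.SeedSequence(seed)
    r2 = np.empty(n_seeds)
    for i, child in enumerate(root.spawn(n_seeds)):
        pipeline, reference = [], []
        for (spec, fat, water, truth), sigma, grand in zip(
            design, sigmas, child.spawn(len(design))
        ):
            sim_seed, ref_seed = grand.generate_state(2).tolist()
            noisy = replace(spec, sigma=sigma)
            fs, ws = phantom.simulate_chess_pair(fat, water, noisy, seed=sim_seed)
            q = fatwater.quantify_pair(fs, ws, k=k)
            pipeline.append(q.fat_mass_mg)
            reference.append(
                phantom.simulate_reference_fat_mass(
                    truth.fat_mass_mg, reference_cv, seed=ref_seed
                )
            )
        r2[i] = pearson_r2(PairedMeasurements(np.array(pipeline), np.array(reference)))
    return r2
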