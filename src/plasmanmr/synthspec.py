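"""Synthetic plasma 1H-NMR spectrum and cohort simulator.

Generates frequency-domain spectra with known ground truth under four
observation models that emulate common plasma acquisition strategies:

``noesy_filtered``
    1D NOESY on an ultrafiltered sample: macromolecules are physically
    removed, small molecules pass unattenuated.
``cpmg``
    T2 relaxation editing: every component is attenuated by
    ``exp(-loops * echo_spacing / T2)``; the slowly-relaxing residual of
    macromolecule envelopes survives as a configurable fraction.
``led``
    Diffusion editing at a given gradient fraction ``f``: attenuation
    follows a reduced Stejskal-Tanner form ``exp(-c * f**2 * D)`` where
    ``D`` is the component's relative diffusion coefficient (1 for a fast
    small molecule, near 0 for macromolecules).

Lineshapes are Lorentzian with full width at half maximum specified in Hz
and converted to ppm through the spectrometer frequency.  Noise is iid
Gaussian per point, optionally with an intensity-proportional
(heteroscedastic) term.  All randomness flows from one master seed through
named `numpy` SeedSequence substreams, so cohorts are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectra import Spectrum

__all__ = [
    "MetaboliteSpec",
    "MacromoleculeSpec",
    "InternalStandardSpec",
    "AcquisitionConfig",
    "ObservationModel",
    "ComponentSet",
    "CohortDesign",
    "render_spectrum",
    "simulate_cohort",
    "simulate_standard_addition",
    "simulate_repeatability",
    "default_plasma_components",
    "default_standard",
    "standard_addition_stock",
]

#: reduced Stejskal-Tanner instrument constant; calibrated so that a
#: D=1 small molecule keeps >99.5% of its signal at 2% gradient and
#: loses >99% at 70% gradient.
DEFAULT_GRADIENT_CONSTANT = 10.0

#: volumetric dilution of the standard-addition spike: 100 uL of stock
#: added to 400 uL of plasma (1:5 into the 500 uL plasma phase).
SPIKE_DILUTION = 5.0


@dataclass
class MetaboliteSpec:
    """A small-molecule component with a Lorentzian multiplet.

    ``multiplet`` is a list of ``(center_ppm, relative_area, fwhm_hz)``
    tuples; relative areas are proportional to proton counts.
    ``diffusion`` is the relative diffusion coefficient in [0, 1] and
    ``t2`` the transverse relaxation time in seconds.  ``bound_fraction``
    is the protein-bound (NMR-invisible) fraction of the metabolite.
    """

    name: str
    multiplet: list[tuple[float, float, float]]
    diffusion: float = 1.0
    t2: float = 1.5
    concentration_by_group: dict[str, float] = field(default_factory=dict)
    replicate_cv: float = 0.0
    bound_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not self.multiplet:
            raise ValueError(f"{self.name}: multiplet must be non-empty")
        if sum(a for _, a, _ in self.multiplet) <= 0:
            raise ValueError(f"{self.name}: relative areas must sum > 0")
        if any(w <= 0 for _, _, w in self.multiplet):
            raise ValueError(f"{self.name}: every fwhm must be > 0")
        if not 0.0 <= self.diffusion <= 1.0:
            raise ValueError(f"{self.name}: diffusion must lie in [0, 1]")
        if self.t2 <= 0:
            raise ValueError(f"{self.name}: t2 must be > 0")
        if not 0.0 <= self.bound_fraction < 1.0:
            raise ValueError(f"{self.name}: bound_fraction must lie in [0, 1)")

    @property
    def total_area(self) -> float:
        return float(sum(a for _, a, _ in self.multiplet))


@dataclass
class MacromoleculeSpec:
    """A broad macromolecule envelope (protein / lipoprotein humps)."""

    name: str
    humps: list[tuple[float, float, float]]  # (center_ppm, area, fwhm_hz)
    diffusion: float = 0.002
    t2: float = 0.3
    cpmg_residual_fraction: float = 0.25

    def __post_init__(self) -> None:
        if not self.humps:
            raise ValueError(f"{self.name}: humps must be non-empty")
        if any(w <= 20.0 for _, _, w in self.humps):
            raise ValueError(f"{self.name}: every hump fwhm must be > 20 Hz")
        if not 0.0 <= self.cpmg_residual_fraction <= 1.0:
            raise ValueError(f"{self.name}: cpmg_residual_fraction in [0,1]")


@dataclass
class InternalStandardSpec:
    """Internal quantification standard (maleic acid or TSP).

    The linewidth depends on whether the sample was ultrafiltered:
    TSP binds plasma protein and broadens markedly in unfiltered samples
    whereas maleic acid does not.
    """

    name: str = "MA"
    center: float = 6.0
    concentration: float = 0.43
    fwhm_filtered: float = 1.0
    fwhm_unfiltered: float = 1.0
    diffusion: float = 1.0
    t2: float = 2.0

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise ValueError("standard concentration must be > 0")
        if self.fwhm_filtered <= 0 or self.fwhm_unfiltered <= 0:
            raise ValueError("standard linewidths must be > 0")


@dataclass
class AcquisitionConfig:
    n_points: int = 32768
    ppm_range: tuple[float, float] = (-0.5, 10.8)
    spectrometer_freq: float = 500.13
    noise_sd: float = 1.0
    heteroscedastic_frac: float = 0.0  # extra noise sd per unit intensity
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        if self.ppm_range[0] >= self.ppm_range[1]:
            raise ValueError("ppm_range must satisfy min < max")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def axis(self) -> np.ndarray:
        return np.linspace(self.ppm_range[0], self.ppm_range[1], self.n_points)


@dataclass
class ObservationModel:
    """Which pulse-sequence surrogate to apply when rendering."""

    kind: str  # noesy_filtered | cpmg | led
    gradient_fraction: float | None = None
    gradient_constant: float = DEFAULT_GRADIENT_CONSTANT
    cpmg_loops: int = 300
    echo_spacing: float = 0.001

    def __post_init__(self) -> None:
        if self.kind not in {"noesy_filtered", "cpmg", "led"}:
            raise ValueError(f"unknown observation model kind {self.kind!r}")
        if self.kind == "led":
            if self.gradient_fraction is None:
                raise ValueError("led requires a gradient_fraction")
            if not 0.0 <= self.gradient_fraction <= 1.0:
                raise ValueError("gradient_fraction must lie in [0, 1]")
        elif self.gradient_fraction is not None:
            raise ValueError("gradient_fraction only applies to led")
        if self.gradient_constant <= 0:
            raise ValueError("gradient_constant must be > 0")

    @property
    def is_filtered(self) -> bool:
        return self.kind == "noesy_filtered"


LED_LOW = ObservationModel(kind="led", gradient_fraction=0.02)
LED_HIGH = ObservationModel(kind="led", gradient_fraction=0.70)
NOESY = ObservationModel(kind="noesy_filtered")
CPMG = ObservationModel(kind="cpmg")


@dataclass
class ComponentSet:
    metabolites: list[MetaboliteSpec]
    macromolecules: list[MacromoleculeSpec] = field(default_factory=list)

    def metabolite(self, name: str) -> MetaboliteSpec:
        for m in self.metabolites:
            if m.name == name:
                return m
        raise KeyError(name)


@dataclass
class CohortDesign:
    """Two-group replicate cohort layout.

    ``groups`` maps group label to a per-metabolite concentration
    multiplier map (metabolites not listed keep multiplier 1).
    """

    groups: dict[str, dict[str, float]]
    n_replicates: dict[str, int]
    batch_effect_sd: float = 0.0
    batches: dict[str, int] | None = None  # sample id -> batch index

    def __post_init__(self) -> None:
        if set(self.groups) != set(self.n_replicates):
            raise ValueError("groups and n_replicates must list the same groups")
        if any(n < 1 for n in self.n_replicates.values()):
            raise ValueError("every group needs at least one replicate")
        if self.batch_effect_sd < 0:
            raise ValueError("batch_effect_sd must be >= 0")

    def sample_ids(self) -> list[str]:
        ids = []
        for g in self.groups:
            ids.extend(f"{g}_{i + 1:02d}" for i in range(self.n_replicates[g]))
        return ids


# ---------------------------------------------------------------------------
# rendering


def _lorentzian(ppm: np.ndarray, center: float, fwhm_hz: float, freq: float) -> np.ndarray:
    """Unit-area Lorentzian on the ppm axis, width given in Hz."""
    hw = fwhm_hz / freq / 2.0
    return (hw / math.pi) / ((ppm - center) ** 2 + hw * hw)


def attenuation(obs: ObservationModel, diffusion: float, t2: float,
                macromolecule: bool = False,
                cpmg_residual_fraction: float = 1.0) -> float:
    """Signal fraction surviving the observation model for one component."""
    if obs.kind == "noesy_filtered":
        return 0.0 if macromolecule else 1.0
    if obs.kind == "cpmg":
        a = math.exp(-obs.cpmg_loops * obs.echo_spacing / t2)
        if macromolecule:
            a *= cpmg_residual_fraction
        return a
    # led
    f = obs.gradient_fraction
    return math.exp(-obs.gradient_constant * f * f * diffusion)


def render_spectrum(
    components: ComponentSet,
    standard: InternalStandardSpec | None,
    acq: AcquisitionConfig,
    obs: ObservationModel,
    concentrations: dict[str, float] | None = None,
    rng: np.random.Generator | None = None,
    group: str | None = None,
    meta: dict | None = None,
) -> Spectrum:
    """Render one noisy spectrum for a sample under one observation model.

    ``concentrations`` overrides per-metabolite concentrations (mM); when
    absent the group entry of ``concentration_by_group`` is used.
    """
    ppm = acq.axis()
    lo, hi = acq.ppm_range
    signal = np.zeros_like(ppm)

    for met in components.metabolites:
        if concentrations is not None and met.name in concentrations:
            conc = concentrations[met.name]
        elif group is not None and met.name not in (concentrations or {}):
            conc = met.concentration_by_group.get(group, 0.0)
        else:
            conc = met.concentration_by_group.get(group, 0.0) if group else 0.0
        if conc == 0.0:
            continue
        # the protein-bound fraction is NMR-invisible in unfiltered samples
        # and removed together with the protein by ultrafiltration
        visible = conc * (1.0 - met.bound_fraction)
        att = attenuation(obs, met.diffusion, met.t2)
        if visible * att == 0.0:
            continue
        for center, area, fwhm in met.multiplet:
            if not lo <= center <= hi:
                raise ValueError(
                    f"{met.name}: multiplet center {center} ppm outside "
                    f"ppm_range {acq.ppm_range}"
                )
            signal += visible * att * area * _lorentzian(ppm, center, fwhm, acq.spectrometer_freq)

    for mac in components.macromolecules:
        att = attenuation(obs, mac.diffusion, mac.t2, macromolecule=True,
                          cpmg_residual_fraction=mac.cpmg_residual_fraction)
        if att == 0.0:
            continue
        for center, area, fwhm in mac.humps:
            if not lo <= center <= hi:
                raise ValueError(
                    f"{mac.name}: hump center {center} ppm outside ppm_range"
                )
            signal += att * area * _lorentzian(ppm, center, fwhm, acq.spectrometer_freq)

    if standard is not None:
        fwhm = standard.fwhm_filtered if obs.is_filtered else standard.fwhm_unfiltered
        att = attenuation(obs, standard.diffusion, standard.t2)
        signal += standard.concentration * att * _lorentzian(
            ppm, standard.center, fwhm, acq.spectrometer_freq
        )

    if acq.noise_sd > 0 or acq.heteroscedastic_frac > 0:
        if rng is None:
            rng = np.random.default_rng(acq.seed)
        sd = acq.noise_sd + acq.heteroscedastic_frac * np.abs(signal)
        signal = signal + rng.normal(0.0, 1.0, signal.shape) * sd

    md = {
        "method": obs.kind,
        "gradient_fraction": obs.gradient_fraction,
        "spectrometer_freq": acq.spectrometer_freq,
    }
    if group is not None:
        md["group"] = group
    if meta:
        md.update(meta)
    return Spectrum(ppm=ppm, intensity=signal, meta=md)


# ---------------------------------------------------------------------------
# cohort and QC designs


def _draw_concentrations(
    components: ComponentSet,
    group: str,
    multipliers: dict[str, float],
    rng: np.random.Generator,
) -> dict[str, float]:
    """Log-normal replicate draw around the group design concentration."""
    out = {}
    for met in components.metabolites:
        base = met.concentration_by_group.get(group, 0.0)
        base *= multipliers.get(met.name, 1.0)
        if base <= 0:
            out[met.name] = 0.0
            continue
        cv = met.replicate_cv
        if cv > 0:
            sigma = math.sqrt(math.log(1.0 + cv * cv))
            out[met.name] = base * rng.lognormal(-0.5 * sigma * sigma, sigma)
        else:
            out[met.name] = base
    return out


def simulate_cohort(
    design: CohortDesign,
    components: ComponentSet,
    acq: AcquisitionConfig,
    obs_list: list[ObservationModel],
    standard: InternalStandardSpec | None = None,
) -> tuple[dict[str, dict[str, Spectrum]], pd.DataFrame]:
    """Simulate a replicate cohort under several observation models.

    Returns ``spectra[sample_id][obs_key]`` plus a ground-truth table of
    the drawn concentrations (samples x metabolites) with group/batch
    columns.  ``obs_key`` is the observation kind, suffixed with the
    gradient percentage for led (e.g. ``led02``, ``led70``).
    """
    if standard is None:
        standard = default_standard()
    sample_ids = design.sample_ids()
    if not sample_ids:
        raise ValueError("design produced no samples")
    streams = np.random.SeedSequence(acq.seed).spawn(len(sample_ids))

    spectra: dict[str, dict[str, Spectrum]] = {}
    rows = []
    for sid, ss in zip(sample_ids, streams):
        group = sid.rsplit("_", 1)[0]
        rng = np.random.default_rng(ss)
        conc = _draw_concentrations(components, group, design.groups[group], rng)
        batch = 0 if design.batches is None else design.batches.get(sid, 0)
        scale = 1.0
        if design.batch_effect_sd > 0:
            # shared multiplicative batch factor, reproducible per batch
            brng = np.random.default_rng(
                np.random.SeedSequence([acq.seed, 7919, batch])
            )
            scale = float(brng.lognormal(0.0, design.batch_effect_sd))
        scaled = {k: v * scale for k, v in conc.items()}
        per_obs = {}
        for obs in obs_list:
            key = obs_key(obs)
            per_obs[key] = render_spectrum(
                components, standard, acq, obs,
                concentrations=scaled, rng=rng, group=group,
                meta={"sample_id": sid, "batch": batch},
            )
        spectra[sid] = per_obs
        rows.append({"sample_id": sid, "group": group, "batch": batch, **conc})
    truth = pd.DataFrame(rows).set_index("sample_id")
    return spectra, truth


def obs_key(obs: ObservationModel) -> str:
    if obs.kind == "led":
        return f"led{round(obs.gradient_fraction * 100):02d}"
    return obs.kind


def simulate_standard_addition(
    qc_components: ComponentSet,
    stock: dict[str, float],
    levels: tuple[float | None, ...] = (1.0, 3.0, 5.0, 10.0, None),
    n_reps: int = 3,
    acq: AcquisitionConfig | None = None,
    obs_list: list[ObservationModel] | None = None,
    standard: InternalStandardSpec | None = None,
    qc_group: str = "QC",
) -> tuple[dict[str, dict[str, Spectrum]], pd.DataFrame, pd.DataFrame]:
    """Simulate the standard-addition series: spike stock dilutions into QC plasma.

    ``levels`` lists dilution factors of the master stock; ``None`` is the
    water blank.  Each level is added to ``n_reps`` QC aliquots.  The
    plasma-phase added amount is ``stock / dilution / 5`` (100 uL of spike
    into 500 uL total).  Defaults give 5 levels x 3 replicates = 15 samples.
    """
    if not levels:
        raise ValueError("levels must be non-empty")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if any(l is not None and l <= 0 for l in levels):
        raise ValueError("dilution factors must be > 0")
    if acq is None:
        acq = AcquisitionConfig()
    if obs_list is None:
        obs_list = [LED_LOW, LED_HIGH]
    if standard is None:
        standard = default_standard()

    sample_ids = []
    added_rows = []
    for li, level in enumerate(levels):
        for r in range(n_reps):
            tag = "blank" if level is None else f"{level:g}x"
            sid = f"sa_{tag}_{r + 1}"
            sample_ids.append((sid, level))
            added = {
                name: (0.0 if level is None else conc / level / SPIKE_DILUTION)
                for name, conc in stock.items()
            }
            added_rows.append({"sample_id": sid, "level": tag, **added})
    added_df = pd.DataFrame(added_rows).set_index("sample_id")

    streams = np.random.SeedSequence([acq.seed, 104729]).spawn(len(sample_ids))
    spectra: dict[str, dict[str, Spectrum]] = {}
    truth_rows = []
    for (sid, level), ss in zip(sample_ids, streams):
        rng = np.random.default_rng(ss)
        conc = _draw_concentrations(qc_components, qc_group, {}, rng)
        total = {
            name: conc.get(name, 0.0) + added_df.loc[sid].get(name, 0.0)
            for name in {m.name for m in qc_components.metabolites}
        }
        per_obs = {}
        for obs in obs_list:
            per_obs[obs_key(obs)] = render_spectrum(
                qc_components, standard, acq, obs,
                concentrations=total, rng=rng, group=qc_group,
                meta={"sample_id": sid, "level": added_df.loc[sid, "level"]},
            )
        spectra[sid] = per_obs
        truth_rows.append({"sample_id": sid, "level": added_df.loc[sid, "level"], **total})
    truth = pd.DataFrame(truth_rows).set_index("sample_id")
    return spectra, truth, added_df


def simulate_repeatability(
    qc_components: ComponentSet,
    n_batches: int = 45,
    per_batch: int = 1,
    acq: AcquisitionConfig | None = None,
    obs_list: list[ObservationModel] | None = None,
    standard: InternalStandardSpec | None = None,
    batch_effect_sd: float = 0.0,
    qc_group: str = "QC",
) -> tuple[dict[str, dict[str, Spectrum]], pd.DataFrame]:
    """Simulate QC repeatability runs (default inter-batch: 45 batches x 1 QC).

    The intra-batch design is ``n_batches=1, per_batch=19``.  A
    multiplicative log-normal batch factor with sd ``batch_effect_sd``
    is shared by all samples of a batch.
    """
    if n_batches < 1 or per_batch < 1:
        raise ValueError("counts must be >= 1")
    if acq is None:
        acq = AcquisitionConfig()
    if obs_list is None:
        obs_list = [LED_LOW, LED_HIGH]
    if standard is None:
        standard = default_standard()

    design = CohortDesign(
        groups={qc_group: {}},
        n_replicates={qc_group: n_batches * per_batch},
        batch_effect_sd=batch_effect_sd,
        batches={
            f"{qc_group}_{i + 1:02d}": i // per_batch
            for i in range(n_batches * per_batch)
        },
    )
    return simulate_cohort(design, qc_components, acq, obs_list, standard)


# ---------------------------------------------------------------------------
# shipped component libraries


def default_standard(name: str = "MA") -> InternalStandardSpec:
    """Maleic acid (default) or TSP internal standard."""
    if name == "MA":
        return InternalStandardSpec("MA", center=6.0, concentration=0.43,
                                    fwhm_filtered=1.0, fwhm_unfiltered=1.0)
    if name == "TSP":
        return InternalStandardSpec("TSP", center=0.0, concentration=0.5,
                                    fwhm_filtered=1.0, fwhm_unfiltered=11.0)
    raise KeyError(name)


def standard_addition_stock() -> dict[str, float]:
    """Master stock concentrations (mM) for the nine spiked compounds."""
    return {
        "glycine": 5.54,
        "alanine": 2.38,
        "phenylalanine": 4.77,
        "methionine": 0.56,
        "lysine": 3.17,
        "threonine": 1.14,
        "creatine": 1.07,
        "creatinine": 0.99,
        "hypoxanthine": 0.29,
    }


def _met(name, multiplet, conc, cv=0.10, bound=0.0):
    return MetaboliteSpec(
        name=name, multiplet=multiplet, diffusion=1.0, t2=1.5,
        concentration_by_group=conc, replicate_cv=cv, bound_fraction=bound,
    )


def default_plasma_components(
    groups: tuple[str, ...] = ("PA", "PPGL"),
    fold_changes: dict[str, float] | None = None,
    replicate_cv: float = 0.10,
    include_macromolecules: bool = True,
) -> ComponentSet:
    """Plasma-like component library for the two-group replicate cohort.

    Concentrations are typical plasma levels (mM); multiplet positions are
    chosen at the compounds' canonical shifts, avoiding the shipped
    bucket-exclusion regions for the discriminating metabolites.
    ``fold_changes`` maps metabolite name to the multiplier applied to the
    second group relative to the first (default: 2-fold changes on five
    metabolites).
    """
    if fold_changes is None:
        fold_changes = {
            "alanine": 2.0,
            "glycine": 2.0,
            "creatine": 2.0,
            "phenylalanine": 0.5,
            "hypoxanthine": 2.0,
        }
    base = {
        # name: (multiplet, base mM)
        "valine": ([(0.99, 3.0, 1.2), (1.04, 3.0, 1.2)], 0.25),
        "threonine": ([(1.33, 3.0, 1.2), (4.26, 1.0, 1.4)], 0.14),
        "alanine": ([(1.47, 1.5, 1.2), (1.49, 1.5, 1.2)], 0.35),
        "acetone": ([(2.23, 6.0, 1.0)], 0.05),
        "glutamine": ([(2.45, 2.0, 1.6)], 0.55),
        "citrate": ([(2.55, 2.0, 1.4), (2.67, 2.0, 1.4)], 0.11),
        "methionine": ([(2.14, 3.0, 1.1)], 0.03),
        "lysine": ([(2.99, 1.0, 1.2), (3.01, 2.0, 1.2), (3.03, 1.0, 1.2)], 0.18),
        "creatine": ([(3.04, 3.0, 1.0), (3.93, 2.0, 1.2)], 0.04),
        "creatinine": ([(3.05, 3.0, 1.0), (4.06, 2.0, 1.2)], 0.07),
        "glycine": ([(3.56, 2.0, 1.0)], 0.25),
        "glucose": ([(5.21, 1.0, 1.4), (5.23, 1.0, 1.4)], 5.0),
        "histidine": ([(7.10, 1.0, 1.3)], 0.08),
        "phenylalanine": ([(7.31, 2.0, 1.2), (7.37, 3.0, 1.3)], 0.06),
        "formate": ([(8.45, 1.0, 1.0)], 0.03),
        "hypoxanthine": ([(8.19, 1.0, 1.1)], 0.01),
    }
    g0, g1 = groups[0], groups[-1]
    mets = []
    for name, (multiplet, conc) in base.items():
        fc = fold_changes.get(name, 1.0)
        mets.append(_met(
            name, multiplet,
            {g0: conc, g1: conc * fc, "QC": conc},
            cv=replicate_cv,
        ))
    macs = []
    if include_macromolecules:
        macs = [
            MacromoleculeSpec(
                "lipoprotein",
                humps=[(0.88, 60.0, 150.0), (1.28, 80.0, 180.0), (2.05, 40.0, 160.0)],
            ),
            MacromoleculeSpec(
                "glycoprotein",
                humps=[(2.08, 30.0, 120.0), (3.22, 40.0, 220.0)],
            ),
            MacromoleculeSpec(
                "albumin_envelope",
                humps=[(0.95, 50.0, 300.0), (3.75, 30.0, 260.0), (7.2, 25.0, 400.0)],
            ),
        ]
    return ComponentSet(metabolites=mets, macromolecules=macs)


def standard_addition_components(
    replicate_cv: float = 0.03,
    bound_fractions: dict[str, float] | None = None,
) -> ComponentSet:
    """QC plasma library restricted to the nine spiked compounds.

    ``bound_fractions`` assigns protein-bound (invisible) fractions; the
    default leaves every compound fully visible.
    """
    if bound_fractions is None:
        bound_fractions = {}
    base = {
        "glycine": ([(3.56, 2.0, 1.0)], 0.25),
        "alanine": ([(1.47, 1.5, 1.2), (1.49, 1.5, 1.2)], 0.35),
        "phenylalanine": ([(7.31, 2.0, 1.2), (7.37, 3.0, 1.3)], 0.06),
        "methionine": ([(2.14, 3.0, 1.1)], 0.03),
        "lysine": ([(2.99, 1.0, 1.2), (3.01, 2.0, 1.2), (3.03, 1.0, 1.2)], 0.18),
        "threonine": ([(1.33, 3.0, 1.2), (4.26, 1.0, 1.4)], 0.14),
        "creatine": ([(3.04, 3.0, 1.0), (3.93, 2.0, 1.2)], 0.04),
        "creatinine": ([(4.06, 2.0, 1.2), (3.05, 3.0, 1.0)], 0.07),
        "hypoxanthine": ([(8.19, 1.0, 1.1)], 0.01),
    }
    mets = [
        _met(name, multiplet, {"QC": conc}, cv=replicate_cv,
             bound=bound_fractions.get(name, 0.0))
        for name, (multiplet, conc) in base.items()
    ]
    return ComponentSet(metabolites=mets, macromolecules=[])
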