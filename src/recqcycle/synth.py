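"""Seeded synthetic fixtures for every experiment type in the pipeline.

The generator emulates the full experiment set: md-nucleotide binding
series (five concentrations, both nucleotides), an mdADP chasing trace,
single- and multiple-turnover quenched-flow records at the experimental
concentrations, reporter-based Pi-release progress curves across an ATP
titration, and a multinomial mass-spectrometry isotopologue count table.
Default noise levels: 2% of amplitude for fluorescence, +/-0.02 absolute
for fraction cleaved, 1% of final amplitude for Pi traces — chosen so that
fitted standard errors land in the same range as the published
uncertainties.  All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` spawning, so a manifest plus its seed
regenerates every file bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .exchange import ExchangeParams, IsotopologueDistribution, exchange_distribution, \
    reversal_probability
from .globalfit import ExperimentBundle, ExperimentDescriptor
from .scheme import RateConstantSet, default_rates
from .transients import TransientTrace, simulate_md_binding, simulate_md_chase, \
    simulate_pi_release, simulate_quenched_flow
from .traceio import write_trace

__all__ = [
    "NoiseModel",
    "FixtureManifest",
    "add_noise",
    "sample_ms_counts",
    "make_fixture_bundle",
    "default_quench_bundle",
    "DEFAULT_NOISE",
]

_NOISE_KINDS = ("gaussian_relative", "gaussian_absolute", "multinomial")


@dataclass(frozen=True)
class NoiseModel:
    """Per-observable noise description.

    ``gaussian_relative`` magnitudes are fractions of the signal amplitude
    (max - min); ``gaussian_absolute`` magnitudes are in signal units;
    ``multinomial`` magnitude is the ion count.
    """

    kind: str
    magnitude: float
    seed: int

    def __post_init__(self) -> None:
        if self.kind not in _NOISE_KINDS:
            raise ValueError(f"noise kind must be one of {_NOISE_KINDS}")
        if self.magnitude < 0:
            raise ValueError("noise magnitude must be >= 0")
        if self.seed is None:
            raise ValueError("noise seed is mandatory")


#: Default noise magnitudes per observable (seeds are filled in per fixture).
DEFAULT_NOISE = {
    "md_fluorescence": ("gaussian_relative", 0.02),
    "fraction_cleaved": ("gaussian_absolute", 0.02),
    "pi_released": ("gaussian_relative", 0.01),
}


def add_noise(trace: TransientTrace, model: NoiseModel) -> TransientTrace:
    """Return a noisy copy of ``trace``; the input is left unmodified."""
    rng = np.random.default_rng(model.seed)
    if model.kind == "gaussian_relative":
        span = float(trace.signal.max() - trace.signal.min())
        sd = model.magnitude * span
    elif model.kind == "gaussian_absolute":
        sd = model.magnitude
    else:
        raise ValueError("multinomial noise applies to count tables, not traces")
    noisy = trace.signal + rng.normal(0.0, sd, size=trace.signal.shape)
    meta = dict(trace.meta)
    meta.update({"noise_kind": model.kind, "noise_magnitude": model.magnitude,
                 "noise_sd": sd, "noise_seed": model.seed})
    return TransientTrace(trace.time.copy(), noisy, trace.observable, meta)


def sample_ms_counts(dist: IsotopologueDistribution, n_ions: int,
                     background_fraction: float = 0.0, seed: int = 0,
                     background_dist=(0.925, 0.05, 0.025, 0.0)) -> np.ndarray:
    """Multinomial ion counts over the four m/z classes (0, 1, 2, >=3 labels).

    ``background_fraction`` admixes a labeled contaminant distribution
    before sampling, emulating the residual 18O-labeled Pi of enzyme-free
    controls.
    """
    if n_ions < 1:
        raise ValueError("n_ions must be >= 1")
    if not 0.0 <= background_fraction < 1.0:
        raise ValueError("background_fraction must be in [0, 1)")
    L = dist.as_array()
    p = np.array([L[0], L[1], L[2], L[3] + L[4]])
    bg = np.asarray(background_dist, dtype=float)
    p_mix = (1.0 - background_fraction) * p + background_fraction * bg
    rng = np.random.default_rng(seed)
    return rng.multinomial(n_ions, p_mix)


@dataclass
class FixtureManifest:
    condition: str
    seed: int
    version: str
    entries: list = field(default_factory=list)  # dicts: file, descriptor, noise

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True) + "\n"


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] % (2 ** 31)) for child in ss.spawn(n)]


# Experimental concentration sets mirrored by the fixtures (post-mixing, uM).
_QUENCH_CONDITIONS = {
    "dna_bound": {"enzyme": 2.0, "single_atp": 1.5, "multi_atp": 25.0,
                  "grid": (2e-3, 5.0)},
    "dna_free": {"enzyme": 4.0, "single_atp": 3.0, "multi_atp": 50.0,
                 "grid": (2.0, 60.0)},
}
_BINDING_CONCS = (5.0, 10.0, 20.0, 50.0, 100.0)
_PI_RELEASE_ATP = (5.0, 10.0, 25.0, 50.0, 100.0, 200.0)


def _quench_grid(condition: str, n: int = 15) -> np.ndarray:
    lo, hi = _QUENCH_CONDITIONS[condition]["grid"]
    return np.geomspace(lo, hi, n)


def default_quench_bundle(condition: str = "dna_bound", noise_sd: float = 0.02,
                          seed: int = 0,
                          rates: RateConstantSet | None = None) -> ExperimentBundle:
    """Single- plus multiple-turnover quenched-flow bundle at the
    experimental concentrations, with seeded absolute Gaussian noise."""
    rates = rates or default_rates(condition)
    cfg = _QUENCH_CONDITIONS[condition]
    grid = _quench_grid(condition)
    seeds = _spawn_seeds(seed, 2)
    traces, descriptors = [], []
    for atp, s in zip((cfg["single_atp"], cfg["multi_atp"]), seeds):
        clean = simulate_quenched_flow(rates, cfg["enzyme"], atp, grid)
        noisy = (add_noise(clean, NoiseModel("gaussian_absolute", noise_sd, s))
                 if noise_sd > 0 else clean)
        if noise_sd > 0:
            noisy.meta["noise_sd"] = noise_sd
        traces.append(noisy)
        descriptors.append(ExperimentDescriptor("quenched_flow", cfg["enzyme"], atp,
                                                condition))
    return ExperimentBundle(traces, descriptors)


def make_fixture_bundle(condition: str, outdir: Path | str, seed: int,
                        noise: dict | None = None) -> FixtureManifest:
    """Generate the full fixture set for one condition under ``outdir``.

    Produces binding series (5 concentrations x 2 nucleotides), one chase
    trace, single+multiple-turnover quenched-flow traces, Pi-release traces
    at six ATP concentrations and one isotopologue count table, plus a
    ``manifest.json``.  Deterministic per seed; raises if the target
    directory already holds a manifest (output-path collision).
    """
    if condition not in _QUENCH_CONDITIONS:
        raise ValueError("condition must be 'dna_free' or 'dna_bound'")
    noise = {**DEFAULT_NOISE, **(noise or {})}
    outdir = Path(outdir) / condition
    manifest_path = outdir / "manifest.json"
    if manifest_path.exists():
        raise FileExistsError(f"fixture collision: {manifest_path} already exists")
    outdir.mkdir(parents=True, exist_ok=True)

    rates = default_rates(condition)
    rates_md = default_rates(condition, "md_analog")
    n_files = 2 * len(_BINDING_CONCS) + 1 + 2 + len(_PI_RELEASE_ATP) + 1
    seeds = iter(_spawn_seeds(seed, n_files))
    manifest = FixtureManifest(condition=condition, seed=seed, version=__version__)

    def emit(trace: TransientTrace, name: str, observable_noise: str) -> None:
        kind, mag = noise[observable_noise]
        model = NoiseModel(kind, mag, next(seeds))
        noisy = add_noise(trace, model) if mag > 0 else trace
        path = write_trace(noisy, outdir / f"{name}.csv")
        manifest.entries.append({
            "file": path.name,
            "observable": trace.observable,
            "descriptor": {k: v for k, v in trace.meta.items()
                           if not k.startswith("noise_")},
            "noise": {"kind": kind, "magnitude": mag, "seed": model.seed},
        })

    # stopped-flow binding series: 50 log-spaced points, 1 ms - 2 s
    sf_grid = np.geomspace(1e-3, 2.0, 50)
    for nucleotide in ("mdATP", "mdADP"):
        for conc in _BINDING_CONCS:
            k_exp = (rates_md.k1 * conc + rates_md.k_m1 + rates_md.k2
                     if nucleotide == "mdATP" else rates_md.k_m4 * conc + rates_md.k4)
            grid = sf_grid[sf_grid <= 5.0 / k_exp]
            if len(grid) < 12:
                grid = np.geomspace(1e-3, 5.0 / k_exp, 25)
            trace = simulate_md_binding(rates_md, nucleotide, conc, enzyme=1.0,
                                        t_grid=grid)
            emit(trace, f"binding_{nucleotide}_{conc:g}uM", "md_fluorescence")

    chase = simulate_md_chase(rates_md, mdadp_conc=20.0, enzyme=1.0, chase_atp=500.0)
    emit(chase, "chase_mdADP_20uM", "md_fluorescence")

    cfg = _QUENCH_CONDITIONS[condition]
    grid = _quench_grid(condition)
    for tag, atp in (("single", cfg["single_atp"]), ("multi", cfg["multi_atp"])):
        trace = simulate_quenched_flow(rates, cfg["enzyme"], atp, grid)
        emit(trace, f"quench_{tag}_{atp:g}uM", "fraction_cleaved")

    from .scheme import cycle_flux

    for atp in _PI_RELEASE_ATP:
        flux = cycle_flux(rates, atp)
        t_end = min(0.05 * atp / max(0.25 * flux, 1e-9), 20.0)
        t_grid = np.linspace(0.0, max(t_end, 0.5), 40)
        trace = simulate_pi_release(rates, enzyme=0.25, atp=atp, t_grid=t_grid)
        emit(trace, f"pi_release_{atp:g}uM", "pi_released")

    # isotopologue count table
    params = ExchangeParams(f=0.40, p_rev=reversal_probability(rates))
    dist = exchange_distribution(params)
    ms_seed = next(seeds)
    counts = sample_ms_counts(dist, n_ions=20000, seed=ms_seed)
    table = "mz,labels,count\n" + "\n".join(
        f"{mz},{lab},{cnt}" for mz, lab, cnt in
        zip((97, 99, 101, 103), ("0", "1", "2", "3plus"), counts))
    (outdir / "isotopologue_counts.csv").write_text(table + "\n", encoding="utf-8")
    manifest.entries.append({
        "file": "isotopologue_counts.csv",
        "observable": "ms_isotopologues",
        "descriptor": {"f": params.f, "p_rev": params.p_rev, "n_ions": 20000},
        "noise": {"kind": "multinomial", "magnitude": 20000, "seed": ms_seed},
    })

    manifest_path.write_text(manifest.to_json(), encoding="utf-8")
    return manifest
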