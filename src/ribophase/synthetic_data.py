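"""Synthetic paired rDNA/rRNA seasonal communities with known ground truth.

The generator emulates the statistical structure the pipeline is built
for: a multi-year coastal time series where each OTU carries a latent
log-biomass made of a periodic seasonal Gaussian bump plus AR(1)
log-noise; rDNA read weights scale that biomass by a per-group ribosomal
copy-number multiplier, rRNA read weights by a per-OTU activity factor
whose envelope can *lead* the biomass by a configurable number of days
(the anticipatory bloom signal); and libraries are multinomial draws at
realistic depths (defaults ~2x10^4 rDNA / 10^4 rRNA reads per sample).

Presets cover the study designs the tests exercise: a three-guild
seasonal community (spring / summer / winter specialists), a focused
bloom community with one leading taxon, an exchangeable null, and
bivariate log-abundance clouds with a planted reduced-major-axis slope.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .io_tables import OtuTable, TaxonomyMap

DAYS_PER_YEAR = 365.0


@dataclass
class OtuSpec:
    """Ground-truth parameters for one synthetic OTU."""

    otu_id: str
    group: str
    supergroup: str
    baseline_log: float        # log weight away from the seasonal peak
    log_amplitude: float = 0.0  # bump height in log units (0 = flat)
    peak_day: float | None = None  # day-of-year of the seasonal peak
    width_days: float = 30.0
    copy_number: float = 1.0   # rDNA copy-number multiplier c_g > 0
    activity_baseline: float = 1.0
    lead_days: float = 0.0     # activity envelope leads biomass by L days
    closest_relative: str = "synthetic_taxon"


@dataclass
class SyntheticTruth:
    """Full generator configuration: OTUs, dates, depths, noise, seed."""

    otus: list[OtuSpec]
    dates: list[date]
    dna_depth: int = 20000
    rna_depth: int = 10000
    noise_sigma: float = 0.5   # AR(1) log-noise marginal SD (shared by molecules)
    noise_rho: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if len(self.dates) < 2:
            raise ValueError("need at least 2 dates")
        if len(self.otus) < 2:
            raise ValueError("need at least 2 OTUs")
        if self.dna_depth <= 0 or self.rna_depth <= 0:
            raise ValueError("depths must be positive")
        if not 0 <= self.noise_rho < 1:
            raise ValueError("noise_rho must be in [0, 1)")
        for o in self.otus:
            if o.copy_number <= 0:
                raise ValueError(f"{o.otu_id}: copy_number must be > 0")
            if o.activity_baseline <= 0:
                raise ValueError(f"{o.otu_id}: activity_baseline must be > 0")
            if o.lead_days < 0:
                raise ValueError(f"{o.otu_id}: lead_days must be >= 0")
            if o.width_days <= 0:
                raise ValueError(f"{o.otu_id}: width_days must be > 0")


def _bump(day_of_year: np.ndarray, peak: float, width: float) -> np.ndarray:
    """Periodic (annual) Gaussian bump of unit height."""
    delta = np.abs(day_of_year - peak)
    delta = np.minimum(delta, DAYS_PER_YEAR - delta)
    return np.exp(-0.5 * (delta / width) ** 2)


def _log_profiles(truth: SyntheticTruth) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic (noise-free) log weights, dna and rna, OTUs x dates."""
    t = np.array([d.timetuple().tm_yday for d in truth.dates], dtype=float)
    n_otus, n_dates = len(truth.otus), len(truth.dates)
    log_dna = np.empty((n_otus, n_dates))
    log_rna = np.empty((n_otus, n_dates))
    for i, o in enumerate(truth.otus):
        if o.peak_day is None or o.log_amplitude == 0:
            bump_now = np.zeros(n_dates)
            bump_lead = bump_now
        else:
            bump_now = _bump(t, o.peak_day, o.width_days)
            # anticipatory envelope: activity tracks the biomass bump as
            # seen L days into the future, never below the present bump
            bump_lead = np.maximum(bump_now, _bump(t + o.lead_days, o.peak_day, o.width_days))
        log_dna[i] = np.log(o.copy_number) + o.baseline_log + o.log_amplitude * bump_now
        log_rna[i] = (
            np.log(o.activity_baseline) + o.baseline_log + o.log_amplitude * bump_lead
        )
    return log_dna, log_rna


def expected_relative_abundance(truth: SyntheticTruth, molecule: str) -> pd.DataFrame:
    """Noise-free expected relative abundances (dates x OTUs)."""
    log_dna, log_rna = _log_profiles(truth)
    logw = log_dna if molecule == "rDNA" else log_rna
    w = np.exp(logw)
    rel = (w / w.sum(axis=0)).T
    return pd.DataFrame(
        rel, index=pd.to_datetime(truth.dates), columns=[o.otu_id for o in truth.otus]
    )


def simulate_community(
    truth: SyntheticTruth,
) -> tuple[OtuTable, OtuTable, pd.DataFrame, TaxonomyMap]:
    """Draw paired rDNA/rRNA OTU tables from the ground-truth model.

    Returns ``(dna, rna, manifest, taxonomy)``. The AR(1) log-noise is
    shared between the two molecules of a date (it models biomass, not
    library construction), so activity differences are the planted ones
    plus multinomial sampling noise. Row totals equal the configured
    depths exactly; everything is reproducible from ``truth.seed``.
    """
    truth.validate()
    rng = np.random.default_rng(truth.seed)
    n_otus, n_dates = len(truth.otus), len(truth.dates)
    log_dna, log_rna = _log_profiles(truth)

    sigma, rho = truth.noise_sigma, truth.noise_rho
    eps = np.empty((n_otus, n_dates))
    eps[:, 0] = rng.normal(0.0, sigma, size=n_otus)
    innov_sd = sigma * np.sqrt(1 - rho**2)
    for k in range(1, n_dates):
        eps[:, k] = rho * eps[:, k - 1] + rng.normal(0.0, innov_sd, size=n_otus)

    w_dna = np.exp(log_dna + eps)
    w_rna = np.exp(log_rna + eps)
    p_dna = w_dna / w_dna.sum(axis=0)
    p_rna = w_rna / w_rna.sum(axis=0)

    dna_counts = np.empty((n_dates, n_otus), dtype=np.int64)
    rna_counts = np.empty((n_dates, n_otus), dtype=np.int64)
    for k in range(n_dates):
        dna_counts[k] = rng.multinomial(truth.dna_depth, p_dna[:, k])
        rna_counts[k] = rng.multinomial(truth.rna_depth, p_rna[:, k])

    otu_ids = [o.otu_id for o in truth.otus]
    dna_ids = [f"D{k + 1:03d}" for k in range(n_dates)]
    rna_ids = [f"R{k + 1:03d}" for k in range(n_dates)]
    dates = pd.to_datetime(truth.dates)

    dna = OtuTable(
        pd.DataFrame(dna_counts, index=pd.Index(dna_ids, name="sample_id"), columns=otu_ids),
        dates=pd.Series(dates, index=dna_ids),
        molecule=pd.Series("rDNA", index=dna_ids),
    )
    rna = OtuTable(
        pd.DataFrame(rna_counts, index=pd.Index(rna_ids, name="sample_id"), columns=otu_ids),
        dates=pd.Series(dates, index=rna_ids),
        molecule=pd.Series("rRNA", index=rna_ids),
    )
    manifest = pd.DataFrame(
        {
            "library_id": dna_ids + rna_ids,
            "date": list(dates) * 2,
            "molecule": ["rDNA"] * n_dates + ["rRNA"] * n_dates,
            "pair_id": [f"P{k + 1:03d}" for k in range(n_dates)] * 2,
        }
    )
    taxonomy = TaxonomyMap(
        pd.DataFrame(
            {
                "supergroup": [o.supergroup for o in truth.otus],
                "group": [o.group for o in truth.otus],
                "closest_relative": [o.closest_relative for o in truth.otus],
                "pct_identity": 99.0,
            },
            index=pd.Index(otu_ids, name="otu_id"),
        )
    )
    return dna, rna, manifest, taxonomy


def simulate_null(n_samples: int, n_otus: int, depth: int, seed=None) -> OtuTable:
    """Exchangeable null: every sample i.i.d. from one shared multinomial.

    The shared composition is lognormal (a realistic rank-abundance
    shape) drawn once from ``seed``; no structure links samples by
    construction.
    """
    if n_samples < 1 or n_otus < 1 or depth < 1:
        raise ValueError("sizes must be >= 1")
    rng = np.random.default_rng(seed)
    w = np.exp(rng.normal(0.0, 1.0, size=n_otus))
    p = w / w.sum()
    counts = rng.multinomial(depth, p, size=n_samples)
    ids = [f"N{k + 1:03d}" for k in range(n_samples)]
    return OtuTable(
        pd.DataFrame(
            counts, index=pd.Index(ids, name="sample_id"), columns=[f"OTU{j + 1}" for j in range(n_otus)]
        )
    )


def null_proportions(n_otus: int, seed=None) -> np.ndarray:
    """The shared composition that :func:`simulate_null` draws from."""
    rng = np.random.default_rng(seed)
    w = np.exp(rng.normal(0.0, 1.0, size=n_otus))
    return w / w.sum()


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

#: Season centers (day of year) for the three-guild community:
#: spring bloom, summer, winter.
SEASON_CENTERS = {"spring": 105.0, "summer": 215.0, "winter": 355.0}

#: rDNA copy-number multipliers per guild-defining group; dinoflagellate-like
#: groups carry far more ribosomal operons per genome than small flagellates.
GUILD_GROUPS = {
    "spring": ("Haptophyta", "Hacrobia", 5.0),
    "summer": ("Dinophyceae", "Alveolata", 50.0),
    "winter": ("Bacillariophyta", "Stramenopiles", 10.0),
}


def weekly_dates(n_dates: int, start: date = date(2013, 1, 7), interval_days: int = 7) -> list[date]:
    return [start + timedelta(days=interval_days * k) for k in range(n_dates)]


def season_of_dates(dates, centers: dict[str, float] = SEASON_CENTERS) -> pd.Series:
    """Planted season label of each date: nearest season center on the
    circular day-of-year axis."""
    dates = pd.to_datetime(list(dates))
    names = list(centers)
    doy = np.array([d.timetuple().tm_yday for d in dates], dtype=float)
    dist = np.array(
        [
            np.minimum(np.abs(doy - c), DAYS_PER_YEAR - np.abs(doy - c))
            for c in centers.values()
        ]
    )
    labels = [names[i] for i in dist.argmin(axis=0)]
    return pd.Series(labels, index=dates, name="season")


def three_guild_truth(
    n_otus: int = 150,
    n_dates: int = 30,
    interval_days: int = 12,
    seed: int = 0,
    log_amplitude: float = 6.0,
    width_days: float = 40.0,
    peak_jitter_days: float = 10.0,
    dna_depth: int = 20000,
    rna_depth: int = 10000,
) -> SyntheticTruth:
    """Community of three seasonal guilds (spring / summer / winter).

    OTUs split evenly across guilds; each peaks near its guild's season
    center (jittered), rising ~e^6 = 400-fold over baseline in season, so
    samples from different seasons share little read mass and cluster
    apart while samples within a season stay similar. Guild widths of
    ~40 days hand the community over between seasons without leaving any
    date unclaimed by a guild.
    """
    rng = np.random.default_rng(seed)
    seasons = list(SEASON_CENTERS)
    otus = []
    for i in range(n_otus):
        season = seasons[i % 3]
        group, supergroup, copy_number = GUILD_GROUPS[season]
        otus.append(
            OtuSpec(
                otu_id=f"OTU{i + 1}",
                group=group,
                supergroup=supergroup,
                baseline_log=float(rng.normal(0.0, 1.0)),
                log_amplitude=log_amplitude,
                peak_day=float(
                    SEASON_CENTERS[season] + rng.uniform(-peak_jitter_days, peak_jitter_days)
                ),
                width_days=width_days,
                copy_number=copy_number,
                activity_baseline=1.0,
            )
        )
    return SyntheticTruth(
        otus=otus,
        dates=weekly_dates(n_dates, interval_days=interval_days),
        dna_depth=dna_depth,
        rna_depth=rna_depth,
        seed=seed,
    )


def bloom_truth(
    lead_days: float = 21.0,
    n_background: int = 60,
    n_dates: int = 30,
    interval_days: int = 7,
    seed: int = 0,
    peak_day: float = 105.0,
    width_days: float = 10.0,
    baseline_rel: float = 2e-5,
    peak_rel: float = 0.03,
    dna_depth: int = 20000,
    rna_depth: int = 10000,
) -> SyntheticTruth:
    """One bloom-forming taxon over a flat background community.

    The bloom OTU rises from ~0.002% to ~3% of reads around
    ``peak_day``; its activity envelope leads biomass by ``lead_days``,
    so the rRNA signal crosses any abundance threshold that many days
    early. Weekly sampling by default. Sampling starts early enough that
    the pre-bloom quiet phase is observed.
    """
    rng = np.random.default_rng(seed)
    otus = [
        OtuSpec(
            otu_id=f"BG{i + 1}",
            group="Dinophyceae",
            supergroup="Alveolata",
            baseline_log=float(rng.normal(0.0, 1.0)),
        )
        for i in range(n_background)
    ]
    # background total weight ~ n_background * E[e^N(0,1)]
    bg_total = n_background * float(np.exp(0.5))
    baseline_log = float(np.log(baseline_rel * bg_total))
    amplitude = float(np.log(peak_rel / baseline_rel))
    otus.append(
        OtuSpec(
            otu_id="BLOOM",
            group="Haptophyta",
            supergroup="Hacrobia",
            baseline_log=baseline_log,
            log_amplitude=amplitude,
            peak_day=peak_day,
            width_days=width_days,
            copy_number=1.0,
            activity_baseline=1.0,
            lead_days=lead_days,
            closest_relative="Phaeocystis_globosa",
        )
    )
    return SyntheticTruth(
        otus=otus,
        dates=weekly_dates(n_dates, start=date(2013, 1, 6), interval_days=interval_days),
        dna_depth=dna_depth,
        rna_depth=rna_depth,
        noise_sigma=0.3,
        seed=seed,
    )


def rma_points(
    slope: float,
    intercept: float = 0.0,
    n: int = 300,
    rho: float = 0.9,
    x_mean: float = -3.0,
    x_sd: float = 0.8,
    seed=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Bivariate log-abundance cloud with a planted RMA slope.

    Draws (x, y) bivariate normal with correlation ``rho`` and marginal
    SDs ``x_sd`` and ``slope * x_sd``, so the population reduced-major-axis
    slope is exactly ``slope`` whatever the correlation.
    """
    if not 0 < rho <= 1:
        raise ValueError("rho must be in (0, 1]")
    rng = np.random.default_rng(seed)
    z1 = rng.normal(size=n)
    z2 = rho * z1 + np.sqrt(1 - rho**2) * rng.normal(size=n)
    x = x_mean + x_sd * z1
    y = intercept + slope * x_mean + slope * x_sd * z2
    return x, y
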