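"""Seeded synthetic cohorts: spectra from signature mixtures plus coupled features.

The generative model mirrors the statistical structure the analysis assumes.
Each sample draws baseline signature exposures from a Dirichlet; each causal
signature carries a scalar latent activity, log-normal across the cohort, whose
normal score tilts that signature's exposure share through a bounded saturating
link; channel counts are a multinomial draw from the resulting mixture profile;
and every observed feature is a linear function of the normal score of its
causal signature's activity plus Gaussian noise sized so the realized
feature-activity correlation matches the requested coupling.  "Methylation"
style features anti-coupled to an expression feature are generated as noisy
negative transforms of that feature.  A truth record keeps the latent
activities, exposures and mutation counts for oracle checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import channels as ch
from .catalog import SignatureCatalog
from .errors import ConfigError, RetryExhaustedError
from .spectrum import SpectrumSet

# saturating exposure link: share = SHARE_CAP * Phi(z / SHARE_SCALE)
SHARE_CAP = 0.75
SHARE_SCALE = 1.5
TOTAL_SHARE_CAP = 0.9


@dataclass
class CausalLink:
    """Couples one observed feature to one signature's latent activity.

    ``coupling`` is the target Pearson correlation between the feature and the
    activity's normal score (negative for inverse drivers such as a repair
    gene whose loss is mutagenic).  ``noise_sd`` defaults to
    sqrt(1 - coupling^2), which realizes exactly that correlation in
    expectation.  ``binary=True`` thresholds the noisy latent at the
    (1 - binary_rate) quantile to yield a mutated/wild-type flag.
    """

    feature: str
    signature: str
    coupling: float
    noise_sd: float | None = None
    binary: bool = False
    binary_rate: float = 0.1

    def __post_init__(self):
        if not -1.0 <= self.coupling <= 1.0:
            raise ConfigError(f"coupling {self.coupling} outside [-1, 1]")
        if abs(self.coupling) == 1.0 and self.noise_sd not in (None, 0.0):
            raise ConfigError("coupling of +/-1 is infeasible with noise_sd > 0")


@dataclass
class AntiFeature:
    """A feature generated as a noisy negative transform of another feature."""

    name: str
    source: str
    noise_sd: float = 0.1


@dataclass
class MutationCountSpec:
    """Distribution of per-sample mutation counts.

    ``fixed`` draws every sample at ``median``; ``lognormal`` draws
    exp(Normal(log median, sigma)) clipped to [lo, hi].
    """

    kind: str = "lognormal"
    median: float = 500.0
    sigma: float = 1.0
    lo: int = 50
    hi: int = 10_000

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.lo < 1:
            raise ConfigError("mutation count floor must be >= 1")
        if self.kind == "fixed":
            return np.full(n, int(self.median), dtype=np.int64)
        if self.kind == "lognormal":
            raw = rng.lognormal(mean=np.log(self.median), sigma=self.sigma, size=n)
            return np.clip(np.round(raw), self.lo, self.hi).astype(np.int64)
        raise ConfigError(f"unknown mutation count kind {self.kind!r}")


@dataclass
class SimulationConfig:
    n_samples: int
    catalog: SignatureCatalog
    causal_map: list[CausalLink]
    seed: int
    mutations_per_sample: MutationCountSpec = field(default_factory=MutationCountSpec)
    baseline_alpha: np.ndarray | float = 0.5
    anti_features: list[AntiFeature] = field(default_factory=list)
    activity_sigma: float = 1.0

    def __post_init__(self):
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        names = set(self.catalog.names)
        for link in self.causal_map:
            if link.signature not in names:
                raise ConfigError(f"causal signature {link.signature!r} not in catalog")


@dataclass
class CohortTruth:
    """Ground truth of a simulated cohort for oracle-style checks.

    ``scores`` holds the noiseless normal score of each causal signature's
    activity (column ``score_<signature>``); ``exposures`` the realized
    per-sample mixture weights; ``n_mut`` the drawn mutation counts.
    """

    scores: pd.DataFrame
    activities: pd.DataFrame
    exposures: pd.DataFrame
    n_mut: pd.Series


def make_catalog(
    k: int,
    sparsity: float = 0.1,
    seed: int = 0,
    max_cosine: float = 0.8,
    max_tries: int = 1000,
) -> SignatureCatalog:
    """Draw k sparse random signatures with pairwise cosine < ``max_cosine``.

    Profiles are symmetric-Dirichlet draws with concentration ``sparsity``;
    candidates too similar to an accepted profile are rejected.
    """
    if k < 2:
        raise ConfigError("need k >= 2 signatures")
    if not 0 < sparsity <= 1:
        raise ConfigError("sparsity must be in (0, 1]")
    rng = np.random.default_rng(seed)
    rows: list[np.ndarray] = []
    tries = 0
    while len(rows) < k:
        if tries >= max_tries:
            raise RetryExhaustedError(
                f"could not draw {k} signatures below cosine {max_cosine} "
                f"in {max_tries} attempts")
        tries += 1
        cand = rng.dirichlet(np.full(ch.N_CHANNELS, sparsity))
        cn = cand / np.linalg.norm(cand)
        if all(float(cn @ (r / np.linalg.norm(r))) < max_cosine for r in rows):
            rows.append(cand)
    names = [f"SimSig{i + 1:02d}" for i in range(k)]
    return SignatureCatalog.from_matrix(np.vstack(rows), names)


def _exposure_share(z: np.ndarray) -> np.ndarray:
    """Bounded saturating link from a normal score to an exposure share."""
    return SHARE_CAP * stats.norm.cdf(z / SHARE_SCALE)


def simulate_cohort(config: SimulationConfig) -> tuple[SpectrumSet, pd.DataFrame, CohortTruth]:
    """Generate (spectra, features, truth) for one seeded synthetic cohort."""
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    cat = config.catalog
    P = cat.matrix()
    K = cat.k
    sample_ids = pd.Index([f"S{i + 1:04d}" for i in range(n)], name="sample_id")

    n_mut = config.mutations_per_sample.draw(n, rng)

    alpha = (np.asarray(config.baseline_alpha, dtype=float)
             if np.ndim(config.baseline_alpha) else
             np.full(K, float(config.baseline_alpha)))
    if alpha.shape != (K,):
        raise ConfigError(f"baseline_alpha must be scalar or length {K}")
    W0 = rng.dirichlet(alpha, size=n)

    causal_sigs = list(dict.fromkeys(link.signature for link in config.causal_map))
    activities = {}
    scores = {}
    shares = np.zeros((n, len(causal_sigs)))
    for j, sig in enumerate(causal_sigs):
        a = rng.lognormal(mean=0.0, sigma=config.activity_sigma, size=n)
        z = np.log(a)
        z = (z - z.mean()) / z.std()
        activities[f"activity_{sig}"] = a
        scores[f"score_{sig}"] = z
        shares[:, j] = _exposure_share(z)

    total = shares.sum(axis=1)
    over = total > TOTAL_SHARE_CAP
    if over.any():
        shares[over] *= (TOTAL_SHARE_CAP / total[over])[:, None]
        total = shares.sum(axis=1)

    W = W0 * (1.0 - total)[:, None]
    for j, sig in enumerate(causal_sigs):
        W[:, cat.names.index(sig)] += shares[:, j]

    mix = W @ P
    counts = np.vstack([rng.multinomial(int(m), p) for m, p in zip(n_mut, mix)])

    feats = {}
    for link in config.causal_map:
        z = scores[f"score_{link.signature}"]
        c = link.coupling
        ns = np.sqrt(max(1.0 - c * c, 0.0)) if link.noise_sd is None else link.noise_sd
        latent = c * z + ns * rng.standard_normal(n)
        if link.binary:
            thr = np.quantile(latent, 1.0 - link.binary_rate)
            feats[link.feature] = (latent > thr).astype(float)
        else:
            feats[link.feature] = latent
    for anti in config.anti_features:
        if anti.source not in feats:
            raise ConfigError(f"anti-feature source {anti.source!r} not generated")
        feats[anti.name] = -feats[anti.source] + anti.noise_sd * rng.standard_normal(n)

    features = pd.DataFrame(feats, index=sample_ids)
    count_df = pd.DataFrame(counts, index=sample_ids, columns=ch.CHANNELS)
    meta = pd.DataFrame({"n_snv": n_mut, "tmb": n_mut, "eligible": n_mut >= 50},
                        index=sample_ids)
    spectra = SpectrumSet(counts=count_df, meta=meta)
    truth = CohortTruth(
        scores=pd.DataFrame(scores, index=sample_ids),
        activities=pd.DataFrame(activities, index=sample_ids),
        exposures=pd.DataFrame(W, index=sample_ids, columns=cat.names),
        n_mut=pd.Series(n_mut, index=sample_ids, name="n_mut"),
    )
    return spectra, features, truth


def spectra_to_maf(spectra: SpectrumSet) -> tuple[pd.DataFrame, dict[str, str]]:
    """Render spectrum counts as MAF records plus a matching reference.

    One contig per pyrimidine-centered trinucleotide, built by tiling the
    trinucleotide so that every third position carries the wanted context; a
    channel with count c emits c records at distinct positions.  Re-ingesting
    the table through ``build_spectra`` against the returned contigs reproduces
    the count matrix exactly, and the output is byte-stable for fixed input.
    """
    trinuc_of_channel = []
    for idx in range(ch.N_CHANNELS):
        five, ref, _alt, three = ch.channel_context(idx)
        trinuc_of_channel.append(five + ref + three)

    need: dict[str, int] = {}
    arr = spectra.counts.to_numpy()
    for idx, tri in enumerate(trinuc_of_channel):
        peak = int(arr[:, idx].max()) if len(arr) else 0
        need[tri] = max(need.get(tri, 0), peak)

    contigs = {f"ctx_{tri}": tri * max(m, 1) for tri, m in need.items()}

    rows = []
    for sid in spectra.counts.index:
        row = spectra.counts.loc[sid]
        for idx in range(ch.N_CHANNELS):
            c = int(row.iloc[idx])
            if c == 0:
                continue
            five, ref, alt, three = ch.channel_context(idx)
            tri = trinuc_of_channel[idx]
            positions = 2 + 3 * np.arange(c)
            for pos in positions:
                rows.append((sid, f"ctx_{tri}", int(pos), ref, alt, "SNV"))
    maf = pd.DataFrame(rows, columns=["sample_id", "chrom", "pos", "ref", "alt",
                                      "variant_class"])
    maf = maf.sort_values(["sample_id", "chrom", "pos", "alt"],
                          kind="mergesort").reset_index(drop=True)
    return maf, contigs


def write_maf(spectra: SpectrumSet, maf_path, fasta_path=None) -> tuple[pd.DataFrame, dict[str, str]]:
    """Write simulated spectra as a MAF file (and optionally a FASTA fixture)."""
    from .io import write_fasta, write_maf as _write_maf_table

    maf, contigs = spectra_to_maf(spectra)
    _write_maf_table(maf, maf_path)
    if fasta_path is not None:
        write_fasta(contigs, fasta_path)
    return maf, contigs
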