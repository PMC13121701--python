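"""Synthetic two-factor microarray-like expression data with known ground truth.

Emulates a single-replicate donors x media design on primary endothelial
cells: log-normal baseline intensities, additive per-gene medium and donor
effects on the log2 scale, housekeeping probes with no condition effects,
negative-control probes pinned near the fluorescence floor, and sex-linked
genes (Y-chromosome genes silent in female donors, XIST silent in male
donors).  Every downstream stage of the pipeline is testable against the
emitted ground truth without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Donor", "SimConfig", "SimTruth", "generate", "ConfigError"]

#: gene roles recorded in the ground truth
ROLE_ORDINARY = "ordinary"
ROLE_HKG = "housekeeping"
ROLE_NEGATIVE = "negative"
ROLE_Y = "y_linked"
ROLE_XIST = "xist"


class ConfigError(ValueError):
    """A simulation configuration violates one of its bounds."""


@dataclass(frozen=True)
class Donor:
    """A donor (cell line) with its chromosomal sex."""

    label: str
    sex: str  # "male" | "female"

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ConfigError(f"donor {self.label!r}: sex must be 'male' or 'female', got {self.sex!r}")


def _default_donors() -> tuple[Donor, ...]:
    # three donors, one male -- the sex mix of the emulated study design
    return (Donor("D1302", "male"), Donor("D1309", "female"), Donor("D1314", "female"))


def _default_media() -> tuple[str, ...]:
    return ("EBM", "HIMV", "MCDB", "MCDB-S")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the generator.

    All effect and noise scales are standard deviations on the log2 scale.
    ``sigma_noise`` defaults to 0.25 log2 units, i.e. a technical CV of
    roughly 18% on the raw scale, typical of a well-run two-color array.
    The default effect spreads (medium 0.35, donor 0.30) make the medium
    factor dominate the donor factor while keeping two-fold changes a
    few-percent minority of genes per pairwise contrast, the regime seen in
    real primary-cell culture studies.
    """

    seed: int = 0
    n_genes: int = 2000
    donors: tuple[Donor, ...] = field(default_factory=_default_donors)
    media: tuple[str, ...] = field(default_factory=_default_media)
    sigma_medium: float = 0.35
    sigma_donor: float = 0.30
    sigma_noise: float = 0.25
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    n_hkg: int = 14
    n_negative: int = 12
    floor_level: float = 10.0
    frac_affected_medium: float = 1.0
    frac_affected_donor: float = 1.0
    n_y_genes: int = 10
    n_replicates: int = 1
    # spike-in: fixed log2 effects in exactly one medium, for recovery tests
    n_spiked: int = 0
    spike_log2fc: float = 2.0
    spike_medium: str | None = None

    def validate(self) -> None:
        for name in ("sigma_medium", "sigma_donor", "sigma_noise", "baseline_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("frac_affected_medium", "frac_affected_donor"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.n_genes < 2:
            raise ConfigError(f"n_genes must be >= 2, got {self.n_genes}")
        reserved = self.n_hkg + self.n_negative + self.n_y_genes + 1  # +1 for XIST
        if reserved > self.n_genes:
            raise ConfigError(
                f"n_hkg + n_negative + n_y_genes + 1 (XIST) = {reserved} exceeds n_genes = {self.n_genes}"
            )
        if len(self.donors) < 2 or len(self.media) < 2:
            raise ConfigError("need at least 2 donors and 2 media")
        if self.floor_level <= 0:
            raise ConfigError(f"floor_level must be > 0, got {self.floor_level}")
        if self.n_replicates < 1:
            raise ConfigError(f"n_replicates must be >= 1, got {self.n_replicates}")
        if self.n_spiked:
            if self.spike_medium is None or self.spike_medium not in self.media:
                raise ConfigError(f"spike_medium {self.spike_medium!r} not among media {self.media}")
            if self.n_spiked > self.n_genes - reserved:
                raise ConfigError("n_spiked exceeds the number of ordinary genes")


@dataclass
class SimTruth:
    """Ground truth emitted with a simulated matrix.

    ``medium_effects`` / ``donor_effects`` are genes x levels frames of log2
    effects (re-centered across levels so fold change against the overall
    average is well defined).  ``de_medium`` / ``de_donor`` flag genes with
    any non-zero effect for that factor.  ``role`` gives each gene's
    control-gene role.
    """

    medium_effects: pd.DataFrame
    donor_effects: pd.DataFrame
    de_medium: pd.Series
    de_donor: pd.Series
    role: pd.Series

    def to_frame(self) -> pd.DataFrame:
        out = pd.concat(
            [
                self.role.rename("role"),
                self.de_medium.rename("de_medium"),
                self.de_donor.rename("de_donor"),
                self.medium_effects.add_prefix("medium_effect."),
                self.donor_effects.add_prefix("donor_effect."),
            ],
            axis=1,
        )
        out.index.name = "gene"
        return out


#: log2 SD of the multiplicative jitter applied to negative-control probes
_NEGATIVE_JITTER_SD = 0.1
#: emitted intensities are clipped below this value to keep logs finite
_INTENSITY_FLOOR = 1.0


def _centered_effects(rng: np.random.Generator, n_genes: int, levels: int, sigma: float, affected: np.ndarray) -> np.ndarray:
    """Per-gene, per-level N(0, sigma) draws, re-centered across levels; zero rows for unaffected genes."""
    eff = np.zeros((n_genes, levels))
    if sigma > 0 and affected.any():
        draws = rng.normal(0.0, sigma, size=(int(affected.sum()), levels))
        draws -= draws.mean(axis=1, keepdims=True)
        eff[affected] = draws
    return eff


def generate(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SimTruth]:
    """Simulate an intensity matrix plus annotations and ground truth.

    Returns ``(matrix, samples, genes, truth)`` where ``matrix`` is a
    genes x samples frame of strictly positive intensities, ``samples`` has
    columns ``donor``/``medium``/``sex`` indexed by sample id, and ``genes``
    has ``symbol``/``chromosome``/``hkg_candidate``/``negative_control``
    indexed by gene id.

    The log2 intensity of an ordinary gene g in sample (d, m) is
    ``baseline_g + medium_effect_{g,m} + donor_effect_{g,d} + noise``.
    Same config (including seed) reproduces the output bit for bit.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n = config.n_genes
    media = list(config.media)
    donors = list(config.donors)

    # gene ids and roles: controls first, then ordinary genes
    roles = np.array([ROLE_ORDINARY] * n, dtype=object)
    symbols = np.array([f"GENE{i:05d}" for i in range(n)], dtype=object)
    chroms = np.array(["1"] * n, dtype=object)
    pos = 0
    hkg_idx = np.arange(pos, pos + config.n_hkg)
    roles[hkg_idx] = ROLE_HKG
    symbols[hkg_idx] = [f"HKG{i:02d}" for i in range(config.n_hkg)]
    pos += config.n_hkg
    neg_idx = np.arange(pos, pos + config.n_negative)
    roles[neg_idx] = ROLE_NEGATIVE
    symbols[neg_idx] = [f"NEG{i:02d}" for i in range(config.n_negative)]
    pos += config.n_negative
    y_idx = np.arange(pos, pos + config.n_y_genes)
    roles[y_idx] = ROLE_Y
    symbols[y_idx] = [f"YG{i:02d}" for i in range(config.n_y_genes)]
    chroms[y_idx] = "Y"
    pos += config.n_y_genes
    xist_idx = pos
    roles[xist_idx] = ROLE_XIST
    symbols[xist_idx] = "XIST"
    chroms[xist_idx] = "X"
    gene_ids = pd.Index([f"g{i:05d}" for i in range(n)], name="gene")
    ordinary = roles == ROLE_ORDINARY

    # sample layout: one column per donor x medium (x replicate)
    records = []
    for d in donors:
        for m in media:
            for r in range(config.n_replicates):
                sid = f"{m}_{d.label}" + (f"_r{r + 1}" if config.n_replicates > 1 else "")
                records.append((sid, d.label, m, d.sex))
    samples = pd.DataFrame(records, columns=["sample", "donor", "medium", "sex"]).set_index("sample")

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n)

    affected_m = ordinary & (rng.random(n) < config.frac_affected_medium) & (config.sigma_medium > 0)
    affected_d = ordinary & (rng.random(n) < config.frac_affected_donor) & (config.sigma_donor > 0)
    med_eff = _centered_effects(rng, n, len(media), config.sigma_medium, affected_m)
    don_eff = _centered_effects(rng, n, len(donors), config.sigma_donor, affected_d)

    if config.n_spiked:
        free = np.flatnonzero(ordinary & ~affected_m)
        if len(free) < config.n_spiked:
            raise ConfigError("not enough unaffected ordinary genes to spike")
        spiked = rng.choice(free, size=config.n_spiked, replace=False)
        m_col = media.index(config.spike_medium)
        vec = np.zeros(len(media))
        vec[m_col] = config.spike_log2fc
        vec -= vec.mean()  # re-centering preserves all pairwise differences
        med_eff[spiked] = vec
        affected_m[spiked] = True

    m_of = np.array([media.index(m) for m in samples["medium"]])
    d_of = np.array([donors.index(next(x for x in donors if x.label == lbl)) for lbl in samples["donor"]])
    log2 = baseline[:, None] + med_eff[:, m_of] + don_eff[:, d_of]
    if config.sigma_noise > 0:
        log2 = log2 + rng.normal(0.0, config.sigma_noise, size=log2.shape)

    # control-gene overrides on the log2 scale
    log2_floor = np.log2(config.floor_level)
    if config.n_negative:
        log2[neg_idx] = log2_floor + rng.normal(0.0, _NEGATIVE_JITTER_SD, size=(config.n_negative, log2.shape[1]))
    female = (samples["sex"] == "female").to_numpy()
    male = ~female
    if config.n_y_genes:
        log2[np.ix_(y_idx, np.flatnonzero(female))] = log2_floor + rng.normal(
            0.0, _NEGATIVE_JITTER_SD, size=(config.n_y_genes, int(female.sum()))
        )
    log2[xist_idx, male] = log2_floor + rng.normal(0.0, _NEGATIVE_JITTER_SD, size=int(male.sum()))

    intensities = np.maximum(np.exp2(log2), _INTENSITY_FLOOR)
    matrix = pd.DataFrame(intensities, index=gene_ids, columns=samples.index)

    genes = pd.DataFrame(
        {
            "symbol": symbols,
            "chromosome": chroms,
            "hkg_candidate": roles == ROLE_HKG,
            "negative_control": roles == ROLE_NEGATIVE,
        },
        index=gene_ids,
    )

    truth = SimTruth(
        medium_effects=pd.DataFrame(med_eff, index=gene_ids, columns=media),
        donor_effects=pd.DataFrame(don_eff, index=gene_ids, columns=[d.label for d in donors]),
        de_medium=pd.Series(np.abs(med_eff).sum(axis=1) > 0, index=gene_ids),
        de_donor=pd.Series(np.abs(don_eff).sum(axis=1) > 0, index=gene_ids),
        role=pd.Series(roles, index=gene_ids),
    )
    return matrix, samples, genes, truth
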