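"""Synthetic cervical-smear cohort generator with known ground truth.

Emulates the generative structure the downstream analysis assumes: each
sample's methylome is a convex mixture of cell-type reference profiles
(epithelial / fibroblast / immune), community-type-associated CpGs act on
the mean of a single cell compartment *before* mixing (so their observable
size scales with that compartment's fraction), age adds a linear drift on a
designated probe set, and measurement noise plus detection failures sit on
top.  A paired taxon abundance table is generated so that re-typing it
reproduces the planted L/O labels exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .microbiome import DEFAULT_LACTOBACILLI, assign_community_type

DEFAULT_CELL_TYPES = {
    "epithelial": "epithelial",
    "fibroblast": "fibroblast",
    "immune": "immune",
}

DEFAULT_SPECIES = DEFAULT_LACTOBACILLI + (
    "Gardnerella vaginalis",
    "Atopobium vaginae",
    "Prevotella bivia",
    "Sneathia amnii",
)


@dataclass
class ReferenceProfiles:
    """Per-cell-type mean methylation profiles μ_kj.

    ``mu`` is a cell_type × probe DataFrame of beta means in [0, 1];
    ``compartments`` maps each cell type to its compartment tag
    (epithelial | fibroblast | immune).  For every pair of cell types at
    least ``d`` probes differ by ≥ 0.5 in μ so the mixture is identifiable.
    """

    mu: pd.DataFrame
    compartments: dict[str, str]

    @property
    def cell_types(self) -> list[str]:
        return list(self.mu.index)

    @property
    def probes(self) -> pd.Index:
        return self.mu.columns

    def validate(self, d: int = 50) -> None:
        values = self.mu.to_numpy()
        if values.min() < 0 or values.max() > 1:
            raise ValueError("reference means must lie in [0, 1]")
        k = len(self.mu)
        for a in range(k):
            for b in range(a + 1, k):
                n_disc = int((np.abs(values[a] - values[b]) >= 0.5).sum())
                if n_disc < d:
                    raise ValueError(
                        f"cell types {self.mu.index[a]!r}/{self.mu.index[b]!r} "
                        f"share only {n_disc} discriminating probes (< {d})"
                    )


@dataclass
class CohortConfig:
    """Generative parameters of a synthetic cohort.

    Planted differential CpGs are given as ``(count, effect_size)`` with the
    effect Δ in beta units applied (±, half each by default) to the named
    compartment's mean in O-labelled samples.  ``age_effect`` is
    ``(count, slope)`` with the slope in beta units per year, applied to the
    mixed signal around the age-distribution mean.
    """

    n_samples: int = 300
    n_probes: int = 5000
    prevalence_L: float = 0.52
    age_distribution: tuple[float, float, float, float] = (45.0, 12.0, 18.0, 80.0)
    fraction_concentration: tuple[float, ...] = (8.0, 1.0, 3.0)
    fraction_concentration_O: tuple[float, ...] | None = None
    planted_epithelial_dmcs: tuple[int, float] = (0, 0.15)
    planted_immune_dmcs: tuple[int, float] = (0, 0.15)
    hyper_fraction: float = 0.5
    age_effect: tuple[int, float] = (0, 0.0)
    noise_sd: float = 0.045
    noise_model: str = "gaussian"
    probe_failure_rate: float = 0.002
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.prevalence_L < 1.0:
            raise ValueError("prevalence_L must lie in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.noise_model not in ("gaussian", "beta"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        planted = (
            self.planted_epithelial_dmcs[0]
            + self.planted_immune_dmcs[0]
            + self.age_effect[0]
        )
        if planted > self.n_probes:
            raise ValueError("planted probe sets exceed n_probes")


@dataclass
class SyntheticCohort:
    """A generated cohort: beta matrix, detection p, sample sheet, truth."""

    beta: pd.DataFrame                 # probes × samples
    detection_p: pd.DataFrame          # probes × samples
    sample_sheet: pd.DataFrame         # indexed by sample id
    abundance: pd.DataFrame            # samples × species
    truth: dict = field(default_factory=dict)

    @property
    def labels(self) -> pd.Series:
        return self.sample_sheet["label"]

    @property
    def true_fractions(self) -> pd.DataFrame:
        cols = [c for c in self.sample_sheet.columns if c.startswith("frac_")]
        out = self.sample_sheet[cols].copy()
        out.columns = [c[len("frac_"):] for c in cols]
        return out


def generate_reference_profiles(
    n_probes: int,
    cell_types: dict[str, str] | None = None,
    seed: int = 0,
    d: int = 50,
) -> ReferenceProfiles:
    """Draw per-cell-type mean profiles with guaranteed identifiability.

    Most probes share a bimodal baseline across cell types (small jitter);
    for every unordered pair of cell types a disjoint block of ``d`` probes
    is made strongly discriminating (|μ difference| ≥ 0.7).
    """
    cell_types = dict(cell_types or DEFAULT_CELL_TYPES)
    if len(cell_types) < 2:
        raise ValueError("need at least 2 cell types")
    if n_probes < 100:
        raise ValueError("need at least 100 probes")
    names = list(cell_types)
    k = len(names)
    pairs = [(a, b) for a in range(k) for b in range(a + 1, k)]
    if d * len(pairs) > n_probes:
        raise ValueError(
            f"{d} discriminating probes per pair x {len(pairs)} pairs "
            f"exceed n_probes={n_probes}; reduce d"
        )
    rng = np.random.default_rng(seed)
    # bimodal baseline typical of methylation arrays
    base = np.where(rng.random(n_probes) < 0.5,
                    rng.beta(2, 8, n_probes), rng.beta(8, 2, n_probes))
    mu = np.clip(base[None, :] + rng.normal(0.0, 0.02, (k, n_probes)), 0.0, 1.0)
    pos = 0
    for a, b in pairs:
        block = slice(pos, pos + d)
        hi = rng.uniform(0.85, 0.98, d)
        lo = rng.uniform(0.02, 0.15, d)
        mu[a, block] = hi
        mu[b, block] = lo
        for other in range(k):
            if other not in (a, b):
                mu[other, block] = rng.uniform(0.3, 0.7, d)
        pos += d
    probes = pd.Index([f"cg{j:08d}" for j in range(n_probes)], name="probe")
    refs = ReferenceProfiles(
        mu=pd.DataFrame(mu, index=pd.Index(names, name="cell_type"), columns=probes),
        compartments=cell_types,
    )
    refs.validate(d=d)
    return refs


def _truncated_normal(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(config: CohortConfig, refs: ReferenceProfiles) -> SyntheticCohort:
    """Generate a cohort under ``config`` from the given reference profiles.

    Clean signal per sample i and probe j is β_ij = Σ_k f_ik μ_kj with
    planted compartment effects applied to μ before mixing; observed beta is
    the signal plus noise, clipped to [0, 1].
    """
    config.validate()
    if refs.mu.shape[1] != config.n_probes:
        raise ValueError(
            f"reference has {refs.mu.shape[1]} probes but config.n_probes="
            f"{config.n_probes}"
        )
    rng = np.random.default_rng(config.seed)
    n, p = config.n_samples, config.n_probes
    names = refs.cell_types
    k = len(names)
    comp = np.array([refs.compartments[c] for c in names])

    labels = np.where(rng.random(n) < config.prevalence_L, "L", "O")
    mean_age, sd_age, lo_age, hi_age = config.age_distribution
    ages = _truncated_normal(rng, mean_age, sd_age, lo_age, hi_age, n)

    conc_L = np.asarray(config.fraction_concentration, dtype=float)
    if len(conc_L) != k:
        raise ValueError("fraction_concentration length must match cell types")
    conc_O = np.asarray(config.fraction_concentration_O or conc_L, dtype=float)
    fractions = np.empty((n, k))
    for i in range(n):
        fractions[i] = rng.dirichlet(conc_L if labels[i] == "L" else conc_O)

    mu = refs.mu.to_numpy()  # k × p

    # choose disjoint planted probe sets, restricted so ±Δ shifts stay in [0,1]
    n_epi, d_epi = config.planted_epithelial_dmcs
    n_imm, d_imm = config.planted_immune_dmcs
    n_age, slope_age = config.age_effect
    taken = np.zeros(p, dtype=bool)

    def _pick(count, margin_row):
        if count == 0:
            return np.array([], dtype=int)
        ok = np.flatnonzero(~taken & margin_row)
        if len(ok) < count:
            raise ValueError("not enough eligible probes for planted effects")
        idx = rng.choice(ok, size=count, replace=False)
        taken[idx] = True
        return np.sort(idx)

    epi_row = np.flatnonzero(comp == "epithelial")
    imm_rows = np.flatnonzero(comp == "immune")
    epi_margin = (mu[epi_row].min(axis=0) >= d_epi) & (mu[epi_row].max(axis=0) <= 1 - d_epi)
    imm_margin = (mu[imm_rows].min(axis=0) >= d_imm) & (mu[imm_rows].max(axis=0) <= 1 - d_imm) \
        if len(imm_rows) else np.zeros(p, dtype=bool)
    epi_idx = _pick(n_epi, epi_margin)
    imm_idx = _pick(n_imm, imm_margin)
    age_idx = _pick(n_age, np.ones(p, dtype=bool))

    sign_epi = np.where(rng.random(n_epi) < config.hyper_fraction, 1.0, -1.0)
    sign_imm = np.where(rng.random(n_imm) < config.hyper_fraction, 1.0, -1.0)

    is_O = labels == "O"
    signal = fractions @ mu  # n × p
    # compartment effects: add f_compartment ⊙ (±Δ) for O samples at planted probes
    if n_epi:
        f_epi = fractions[:, epi_row].sum(axis=1)
        signal[np.ix_(is_O, epi_idx)] += np.outer(f_epi[is_O], sign_epi * d_epi)
    if n_imm:
        f_imm = fractions[:, imm_rows].sum(axis=1)
        signal[np.ix_(is_O, imm_idx)] += np.outer(f_imm[is_O], sign_imm * d_imm)
    if n_age:
        signal[:, age_idx] += slope_age * (ages - mean_age)[:, None]

    if config.noise_sd > 0:
        if config.noise_model == "gaussian":
            signal = signal + rng.normal(0.0, config.noise_sd, (n, p))
        else:  # beta noise with matched variance around the signal mean
            m = np.clip(signal, 1e-3, 1 - 1e-3)
            v = config.noise_sd**2
            nu = np.maximum(m * (1 - m) / v - 1, 1e-2)
            signal = rng.beta(m * nu, (1 - m) * nu)
    beta = np.clip(signal, 0.0, 1.0)

    fail = rng.random((n, p)) < config.probe_failure_rate
    detp = rng.uniform(0.0, 0.01, (n, p))
    detp[fail] = rng.uniform(0.01, 1.0, int(fail.sum()))

    sample_ids = pd.Index([f"S{i:04d}" for i in range(n)], name="sample")
    probes = refs.probes
    sheet = pd.DataFrame(
        {"label": labels, "age": ages, "tissue": "cervical_smear"},
        index=sample_ids,
    )
    for j, name in enumerate(names):
        sheet[f"frac_{name}"] = fractions[:, j]
    sheet["true_ic"] = fractions[:, imm_rows].sum(axis=1) if len(imm_rows) else 0.0

    abund_seed = int(rng.integers(0, 2**31 - 1))
    abundance = generate_abundance_table(
        pd.Series(labels, index=sample_ids), seed=abund_seed
    )

    truth = {
        "epithelial_dmcs": pd.Series(sign_epi * d_epi, index=probes[epi_idx]),
        "immune_dmcs": pd.Series(sign_imm * d_imm, index=probes[imm_idx]),
        "age_probes": pd.Series(slope_age, index=probes[age_idx]),
    }
    return SyntheticCohort(
        beta=pd.DataFrame(beta.T, index=probes, columns=sample_ids),
        detection_p=pd.DataFrame(detp.T, index=probes, columns=sample_ids),
        sample_sheet=sheet,
        abundance=abundance,
        truth=truth,
    )


def generate_abundance_table(
    labels: pd.Series,
    species: tuple[str, ...] = DEFAULT_SPECIES,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate relative abundances consistent with given L/O labels.

    L samples receive a total designated-Lactobacillus share drawn from
    U(0.5, 0.95); O samples from U(0.05, 0.49).  Shares are split within the
    Lactobacillus and non-Lactobacillus groups by Dirichlet draws, so
    ``assign_community_type`` on the result reproduces ``labels`` exactly.
    """
    wanted = {s.lower() for s in DEFAULT_LACTOBACILLI}
    lacto_cols = [s for s in species if s.lower() in wanted]
    other_cols = [s for s in species if s.lower() not in wanted]
    if len(lacto_cols) < len(DEFAULT_LACTOBACILLI):
        raise ValueError(
            "species list must include the four designated Lactobacillus species"
        )
    rng = np.random.default_rng(seed)
    n = len(labels)
    is_L = np.asarray(labels) == "L"
    total = np.where(is_L, rng.uniform(0.5, 0.95, n), rng.uniform(0.05, 0.49, n))
    lacto_split = rng.dirichlet((4.0, 1.0, 3.0, 1.0), size=n)
    other_split = rng.dirichlet(np.ones(len(other_cols)), size=n)
    table = np.hstack([
        lacto_split * total[:, None],
        other_split * (1.0 - total)[:, None],
    ])
    out = pd.DataFrame(table, index=labels.index, columns=lacto_cols + other_cols)
    check = assign_community_type(out)["label"].to_numpy()
    assert (check == np.asarray(labels)).all()
    return out
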