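"""Synthetic multi-omics CIS cohort generation.

Emulates the data structure of a clinically-isolated-syndrome (CIS)
cerebrospinal-fluid cohort followed for conversion to clinically defined
multiple sclerosis: a 22-converter / 32-non-converter split, a clinical
chemistry block (leukocyte, mononuclear and polynuclear cell counts,
total protein, CSF/serum albumin ratio, binary oligoclonal-band status),
a ~50-metabolite block with configurable signed class effects, and a
high-dimensional right-skewed (log-normal) protein block with a sparse
set of informative features.  Ground-truth effect identities are
recorded on the generated :class:`~csfomics.containers.OmicsMatrix`.

Also provides synthetic Lorentzian 1D spectra with a 1 mM internal
reference singlet, and the fixed 2x2 contingency fixtures used by the
diagnostic-arithmetic checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import OmicsMatrix
from .diagnostics import ContingencyTable
from .errors import ConfigError, DomainError
from .nmr import MALEIC_ACID_PPM, MALEIC_ACID_PROTONS, Spectrum

#: the 30 most abundant NMR-detectable CSF metabolites, plus padding up
#: to the configured block size
CSF_METABOLITES = [
    "3-hydroxybutyrate", "acetate", "acetoacetate", "alanine", "arginine",
    "aspartate", "citrate", "creatine", "creatinine", "formate", "glucose",
    "glutamate", "glutamine", "glycerol", "histidine", "isoleucine",
    "lactate", "leucine", "lysine", "methyl-isobutyrate", "myo-inositol",
    "N-acetyl-aspartate", "phenylalanine", "proline", "scyllo-inositol",
    "taurine", "threonine", "trimethylamine", "tyrosine", "valine",
]

#: example signed metabolite effects (pooled-SD units) for demo pipelines;
#: converters higher in myo-inositol, glucose and lactate, lower in creatine.
#: The default config plants NO metabolite effects.
EXAMPLE_METABOLITE_EFFECTS = {
    "myo-inositol": 0.8,
    "glucose": 0.6,
    "lactate": 0.5,
    "creatine": -0.5,
}

CHEMISTRY_FEATURES = [
    "leukocytes", "mononuclear", "polynuclear", "total_protein", "q_alb", "ocgb",
]


@dataclass
class CohortConfig:
    """Generative parameters for a synthetic two-class CSF cohort.

    Clinical-chemistry defaults reproduce the converter / non-converter
    summary statistics of a published 22-vs-32 CIS cohort (cells/mm^3 for
    cell counts, mg/dl for total protein, dimensionless albumin ratio).
    """

    n_pos: int = 22   # converters
    n_neg: int = 32   # non-converters
    ocgb_prob_pos: float = 1.00
    ocgb_prob_neg: float = 0.69
    leukocyte_mean_sd_pos: tuple[float, float] = (10.9, 9.1)
    leukocyte_mean_sd_neg: tuple[float, float] = (4.9, 4.9)
    mononuclear_mean_sd_pos: tuple[float, float] = (10.7, 8.8)
    mononuclear_mean_sd_neg: tuple[float, float] = (4.7, 4.7)
    total_protein_mean_sd_pos: tuple[float, float] = (367.7, 96.0)
    total_protein_mean_sd_neg: tuple[float, float] = (374.7, 96.0)
    q_alb_mean_sd_pos: tuple[float, float] = (4.9, 2.0)
    q_alb_mean_sd_neg: tuple[float, float] = (5.2, 1.6)
    n_metabolites: int = 50
    metabolite_effects: dict[str, float] | None = None
    n_proteins: int = 5000
    n_informative_proteins: int = 25
    protein_effect: float = 1.0      # additive shift on the log scale
    protein_log_sd: float = 1.0
    truncate_at_zero: bool = True    # truncate cell-count normals at 0
    seed: int = 0

    def metabolite_names(self) -> list[str]:
        names = CSF_METABOLITES[: self.n_metabolites]
        names += [f"met_{i:03d}" for i in range(len(names), self.n_metabolites)]
        return names

    def protein_names(self) -> list[str]:
        return [f"PROT_{i:04d}" for i in range(self.n_proteins)]

    def validate(self) -> None:
        for name in ("ocgb_prob_pos", "ocgb_prob_neg"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name}={p} outside [0, 1]")
        for name in ("n_pos", "n_neg", "n_metabolites", "n_proteins",
                     "n_informative_proteins"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.n_informative_proteins > self.n_proteins:
            raise ConfigError("n_informative_proteins exceeds n_proteins")
        if self.metabolite_effects:
            known = set(self.metabolite_names())
            bad = set(self.metabolite_effects) - known
            if bad:
                raise ConfigError(f"metabolite effects for unknown features: {sorted(bad)}")

    @classmethod
    def null(cls, **overrides) -> "CohortConfig":
        """A no-effect configuration: identical class distributions everywhere."""
        base = dict(
            ocgb_prob_pos=0.69, ocgb_prob_neg=0.69,
            leukocyte_mean_sd_pos=(4.9, 4.9), leukocyte_mean_sd_neg=(4.9, 4.9),
            mononuclear_mean_sd_pos=(4.7, 4.7), mononuclear_mean_sd_neg=(4.7, 4.7),
            total_protein_mean_sd_pos=(374.7, 96.0),
            total_protein_mean_sd_neg=(374.7, 96.0),
            q_alb_mean_sd_pos=(5.2, 1.6), q_alb_mean_sd_neg=(5.2, 1.6),
            metabolite_effects={}, n_informative_proteins=0,
        )
        base.update(overrides)
        return cls(**base)


def _draw_positive(rng, mean, sd, n, truncate):
    if sd == 0:
        return np.full(n, float(mean))
    if not truncate:
        return rng.normal(mean, sd, size=n)
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, OmicsMatrix]:
    """Draw a synthetic cohort; deterministic given ``config.seed``.

    Returns the clinical cohort table (one row per sample) and the
    combined chemistry + metabolite + protein :class:`OmicsMatrix`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_pos + config.n_neg
    labels = np.array([1] * config.n_pos + [0] * config.n_neg)
    sample_ids = [f"S{i:04d}" for i in range(n)]
    pos = labels == 1

    def per_class(mean_sd_pos, mean_sd_neg, truncate):
        out = np.empty(n)
        out[pos] = _draw_positive(rng, *mean_sd_pos, pos.sum(), truncate)
        out[~pos] = _draw_positive(rng, *mean_sd_neg, (~pos).sum(), truncate)
        return out

    trunc = config.truncate_at_zero
    leuko = per_class(config.leukocyte_mean_sd_pos, config.leukocyte_mean_sd_neg, trunc)
    mono = per_class(config.mononuclear_mean_sd_pos, config.mononuclear_mean_sd_neg, trunc)
    if trunc:
        # mononuclear cannot exceed the total leukocyte count; polynuclear
        # is the remainder (clipped at 0 by construction)
        mono = np.minimum(mono, leuko)
        poly = leuko - mono
    else:
        poly = np.clip(leuko - mono, 0.0, None)
    total_protein = per_class(config.total_protein_mean_sd_pos,
                              config.total_protein_mean_sd_neg, trunc)
    q_alb = per_class(config.q_alb_mean_sd_pos, config.q_alb_mean_sd_neg, trunc)
    ocgb = np.empty(n)
    ocgb[pos] = rng.binomial(1, config.ocgb_prob_pos, size=pos.sum())
    ocgb[~pos] = rng.binomial(1, config.ocgb_prob_neg, size=(~pos).sum())

    cohort = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "label": labels,
            "ocgb": ocgb.astype(int),
            "leukocytes": leuko,
            "mononuclear": mono,
            "polynuclear": poly,
            "total_protein": total_protein,
            "q_alb": q_alb,
        }
    ).set_index("sample_id")

    # metabolite block: unit-variance Gaussian, signed shift for converters
    met_names = config.metabolite_names()
    effects = config.metabolite_effects or {}
    met = rng.normal(size=(n, config.n_metabolites))
    informative: list[str] = []
    for name, eff in effects.items():
        j = met_names.index(name)
        met[pos, j] += eff
        if eff != 0:
            informative.append(name)

    # protein block: log-normal, sparse additive shift on the log scale
    prot_names = config.protein_names()
    log_prot = rng.normal(loc=7.0, scale=config.protein_log_sd,
                          size=(n, config.n_proteins))
    if config.n_informative_proteins:
        idx = rng.choice(config.n_proteins, size=config.n_informative_proteins,
                         replace=False)
        idx.sort()
        log_prot[np.ix_(pos, idx)] += config.protein_effect
        informative += [prot_names[j] for j in idx]
    prot = np.exp(log_prot)

    values = pd.concat(
        [
            cohort[CHEMISTRY_FEATURES].astype(float),
            pd.DataFrame(met, index=cohort.index, columns=met_names),
            pd.DataFrame(prot, index=cohort.index, columns=prot_names),
        ],
        axis=1,
    )
    block = pd.Series(
        ["chemistry"] * len(CHEMISTRY_FEATURES)
        + ["metabolite"] * config.n_metabolites
        + ["protein"] * config.n_proteins,
        index=values.columns,
    )
    matrix = OmicsMatrix(
        values=values,
        labels=pd.Series(labels, index=cohort.index, name="label"),
        block=block,
        informative_features=informative,
    )
    return cohort, matrix


# ---------------------------------------------------------------------------
# synthetic spectra

#: simplified single-resonance peak table (ppm center, protons, FWHM in ppm)
DEFAULT_PEAK_TABLE = {
    "glucose": [(3.40, 2, 0.005)],
    "lactate": [(1.33, 3, 0.005)],
    "myo-inositol": [(3.52, 4, 0.005)],
    "creatine": [(3.03, 3, 0.005)],
}


def _lorentzian(x: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    """Unit-area Lorentzian line."""
    gamma = fwhm / 2.0
    return (gamma / np.pi) / ((x - center) ** 2 + gamma**2)


def generate_spectrum(
    concentrations: dict[str, float],
    peak_table: dict[str, list[tuple[float, int, float]]] | None = None,
    ref_conc: float = 1.0,
    ref_ppm: float = MALEIC_ACID_PPM,
    ref_fwhm: float = 0.005,
    noise_sd: float = 0.0,
    seed: int | None = None,
    ppm_range: tuple[float, float] = (-0.5, 10.0),
    n_points: int = 32768,
) -> Spectrum:
    """Sum-of-Lorentzians synthetic 1D spectrum with a reference singlet.

    Each resonance contributes an area proportional to concentration x
    proton count; the internal standard contributes ``ref_conc`` x 2
    protons at ``ref_ppm``.  Additive Gaussian noise of SD ``noise_sd``.
    """
    peak_table = DEFAULT_PEAK_TABLE if peak_table is None else peak_table
    lo, hi = ppm_range
    x = np.linspace(lo, hi, n_points)
    intensity = ref_conc * MALEIC_ACID_PROTONS * _lorentzian(x, ref_ppm, ref_fwhm)
    for met, conc in concentrations.items():
        if conc < 0:
            raise DomainError(f"negative concentration for {met!r}")
        if met not in peak_table:
            raise ConfigError(f"no peaks listed for metabolite {met!r}")
        for center, protons, fwhm in peak_table[met]:
            if not lo <= center <= hi:
                raise DomainError(
                    f"peak at {center} ppm outside spectral range {ppm_range}"
                )
            intensity = intensity + conc * protons * _lorentzian(x, center, fwhm)
    if noise_sd:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(0.0, noise_sd, size=n_points)
    return Spectrum(ppm=x, intensity=intensity, ref_ppm=ref_ppm, ref_conc=ref_conc)


# ---------------------------------------------------------------------------
# fixed contingency fixtures

def reference_fixtures() -> dict[str, ContingencyTable]:
    """2x2 tables for a 22-converter / 32-non-converter CIS cohort.

    The oligoclonal-band (OCGB) table follows directly from the reported
    positivity counts (22/22 converters, 22/32 non-converters).  Marker
    tables are reconstructed from reported sensitivity/specificity by
    nearest-integer rounding of sens*n_pos and spec*n_neg; the leukocyte
    >4 cells/mm^3 rule from the reported 72% / 41% positive proportions.
    """
    n_pos, n_neg = 22, 32

    def from_sens_spec(sens: float, spec: float) -> ContingencyTable:
        tp = round(sens * n_pos)
        tn = round(spec * n_neg)
        return ContingencyTable(tp=tp, fn=n_pos - tp, fp=n_neg - tn, tn=tn)

    return {
        "ocgb": ContingencyTable(tp=22, fn=0, fp=22, tn=10),
        "mmp13": from_sens_spec(0.41, 0.97),
        "ccl17": from_sens_spec(0.50, 0.94),
        "rarres2": from_sens_spec(0.50, 0.91),
        "leukocyte_gt4": from_sens_spec(0.72, 1.0 - 0.41),
    }
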