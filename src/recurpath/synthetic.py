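"""Synthetic data generators with serialized ground truth.

Every pipeline input can be generated here with known truth, so each stage is
testable offline. The generators emulate the study's conditions: a paired
cohort of 7 patients on a ~760-gene count panel with spike-in controls and
housekeeping genes; a ~373-sample primary-only augmentation cohort whose
histology labels exercise the exclusion filter down to 360 samples; pathway
and GO collections with controlled overlap; planted discriminative genes for
classifier-recovery experiments; a 22-cell-type immune signature; and
exponential survival times with a group-dependent hazard.

Counts are negative-binomial with log-normal gene-specific dispersions and
patient-level random effects; differential genes are shifted in recurrent
samples by a configurable log2 effect. Every generator is a pure function of
its parameters and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from itertools import combinations

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSet, GeneSetCollection
from .normalization import ControlSet


@dataclass
class SyntheticTruth:
    """Ground truth serialized alongside every generated dataset."""

    seed: int
    params: dict = field(default_factory=dict)
    de_genes: dict[str, float] = field(default_factory=dict)  # gene -> true log2 effect
    signal_terms: list[str] = field(default_factory=list)
    signal_genes: dict[str, list[str]] = field(default_factory=dict)  # term -> genes
    immune_fractions: dict[str, dict[str, float]] = field(default_factory=dict)
    survival_hazard_ratio: float | None = None

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: np.ndarray) -> np.ndarray:
    """Negative-binomial draws parameterized by mean and dispersion alpha
    (variance mu + alpha mu^2)."""
    size_param = 1.0 / np.maximum(dispersion, 1e-8)
    p = size_param / (size_param + mu)
    return rng.negative_binomial(size_param, p).astype(float)


# ---------------------------------------------------------------------------
# paired study cohort
# ---------------------------------------------------------------------------

def simulate_paired_cohort(
    n_patients: int = 7,
    n_genes: int = 760,
    de_frac: float = 0.10,
    effect_log2fc: float = 1.5,
    dispersion: float = 0.15,
    n_housekeeping: int = 12,
    seed: int = 0,
) -> tuple[ExpressionMatrix, ControlSet, pd.DataFrame, SyntheticTruth]:
    """Paired primary/recurrent count panel with controls and housekeeping genes.

    Planted DE genes (a ``de_frac`` fraction of the panel) are shifted in
    recurrent samples by ``effect_log2fc`` on the log2 scale, mostly upward
    (9:1 up:down, mirroring the strongly asymmetric published DEG split).
    Housekeeping genes track library size with low dispersion. Positive
    controls sit on the standard 4-fold concentration ladder; negative
    controls are near-zero background.
    """
    if not 0 <= de_frac <= 1:
        raise ValueError("de_frac must lie in [0, 1]")
    if effect_log2fc < 0 or dispersion <= 0:
        raise ValueError("effect_log2fc >= 0 and dispersion > 0 required")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:04d}" for i in range(n_genes - n_housekeeping)]
    hk_genes = [f"HK{i:02d}" for i in range(n_housekeeping)]
    all_genes = genes + hk_genes

    samples, patients, tissue = [], [], []
    for i in range(n_patients):
        pid = f"PT{i+1:02d}"
        for tc, suffix in (("primary", "P"), ("recurrent", "R")):
            samples.append(f"{pid}-{suffix}")
            patients.append(pid)
            tissue.append(tc)

    base_mean = rng.lognormal(mean=5.0, sigma=1.2, size=len(genes))
    gene_disp = rng.lognormal(mean=np.log(dispersion), sigma=0.3, size=len(genes))
    lib_size = rng.lognormal(mean=0.0, sigma=0.25, size=len(samples))
    patient_effect = rng.lognormal(mean=0.0, sigma=0.15, size=(n_patients, len(genes)))

    n_de = int(round(de_frac * len(genes)))
    de_idx = rng.choice(len(genes), size=n_de, replace=False)
    signs = np.where(rng.random(n_de) < 0.9, 1.0, -1.0)
    effects = np.zeros(len(genes))
    effects[de_idx] = signs * effect_log2fc

    counts = np.zeros((len(all_genes), len(samples)))
    for s_idx, (pid, tc) in enumerate(zip(patients, tissue)):
        p_i = int(pid[2:]) - 1
        mu = base_mean * patient_effect[p_i] * lib_size[s_idx]
        if tc == "recurrent":
            mu = mu * np.power(2.0, effects)
        counts[: len(genes), s_idx] = _nb_counts(rng, mu, gene_disp)
    hk_mean = rng.lognormal(mean=7.0, sigma=0.3, size=n_housekeeping)
    for s_idx in range(len(samples)):
        mu = hk_mean * lib_size[s_idx]
        counts[len(genes):, s_idx] = _nb_counts(rng, mu, np.full(n_housekeeping, 0.01))

    matrix = ExpressionMatrix(
        pd.DataFrame(counts, index=all_genes, columns=samples), "raw_counts"
    )
    meta = pd.DataFrame(
        {
            "sample_id": samples,
            "patient_id": patients,
            "tissue_class": tissue,
            "cohort": "study",
            "histology_label": "hcc",
        }
    )

    ladder = np.array([128.0, 32.0, 8.0, 2.0, 0.5, 0.125]) * 60.0
    pos = np.zeros((6, len(samples)))
    for s_idx in range(len(samples)):
        pos[:, s_idx] = _nb_counts(rng, np.maximum(ladder * lib_size[s_idx], 0.5), np.full(6, 0.01)) + 1.0
    neg = rng.poisson(4.0, size=(8, len(samples))).astype(float)
    controls = ControlSet(
        positive_controls=pd.DataFrame(pos, index=[f"POS_{c}" for c in "ABCDEF"], columns=samples),
        negative_controls=pd.DataFrame(neg, index=[f"NEG_{c}" for c in "ABCDEFGH"], columns=samples),
        housekeeping_genes=hk_genes,
    )
    truth = SyntheticTruth(
        seed=seed,
        params={
            "n_patients": n_patients,
            "n_genes": n_genes,
            "de_frac": de_frac,
            "effect_log2fc": effect_log2fc,
            "dispersion": dispersion,
        },
        de_genes={genes[i]: float(effects[i]) for i in sorted(de_idx)},
    )
    return matrix, controls, meta, truth


# ---------------------------------------------------------------------------
# augmentation cohort
# ---------------------------------------------------------------------------

EXCLUDED_HISTOLOGIES = {
    "combined_hcc_ichc": 8,
    "fibrolamellar": 3,
    "recurrent_tissue": 2,
}


def simulate_augmentation_cohort(
    gene_ids: list[str],
    n_total: int = 373,
    exclusions: dict[str, int] | None = None,
    mean_shift_sigma: float = 0.6,
    seed: int = 0,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Primary-only cohort with histology labels for the exclusion filter.

    Per-gene means are deliberately shifted (log-normal factor of spread
    ``mean_shift_sigma``) relative to any paired cohort on the same ids, so
    cross-cohort models must rely on the per-pathway standardization rather
    than absolute levels.
    """
    exclusions = EXCLUDED_HISTOLOGIES if exclusions is None else exclusions
    n_excluded = sum(exclusions.values())
    if n_total <= n_excluded:
        raise ValueError("n_total must exceed the number of excluded samples")
    rng = np.random.default_rng(seed)
    samples = [f"AUG-{i:04d}" for i in range(n_total)]
    labels = ["hcc"] * (n_total - n_excluded)
    for lab, count in exclusions.items():
        labels.extend([lab] * count)
    perm = rng.permutation(n_total)
    labels = [labels[i] for i in perm]

    base_mean = rng.lognormal(mean=5.0, sigma=1.2, size=len(gene_ids))
    shift = rng.lognormal(mean=0.0, sigma=mean_shift_sigma, size=len(gene_ids))
    disp = rng.lognormal(mean=np.log(0.2), sigma=0.3, size=len(gene_ids))
    lib = rng.lognormal(mean=0.0, sigma=0.25, size=n_total)
    counts = np.zeros((len(gene_ids), n_total))
    for s in range(n_total):
        counts[:, s] = _nb_counts(rng, base_mean * shift * lib[s], disp)
    matrix = ExpressionMatrix(pd.DataFrame(counts, index=gene_ids, columns=samples), "raw_counts")
    meta = pd.DataFrame(
        {
            "sample_id": samples,
            "patient_id": samples,
            "tissue_class": "primary",
            "cohort": "augmentation",
            "histology_label": labels,
        }
    )
    return matrix, meta


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------

def simulate_gene_sets(
    gene_ids: list[str],
    n_pathways: int = 20,
    n_go: int = 20,
    size_range: tuple[int, int] = (10, 60),
    seed: int = 0,
) -> GeneSetCollection:
    """Random pathway/GO collections over the panel with natural overlap."""
    rng = np.random.default_rng(seed)
    entries = []
    for cat, prefix, count in (("pathway", "WP", n_pathways), ("go_bp", "GO", n_go)):
        for i in range(count):
            size = int(rng.integers(size_range[0], size_range[1] + 1))
            members = rng.choice(len(gene_ids), size=min(size, len(gene_ids)), replace=False)
            entries.append(
                GeneSet(
                    term_id=f"{prefix}{i:04d}",
                    term_name=f"synthetic {cat} {i}",
                    category=cat,
                    genes=tuple(gene_ids[j] for j in sorted(members)),
                )
            )
    return GeneSetCollection(entries)


def plant_term_signal(
    matrix: ExpressionMatrix,
    collection: GeneSetCollection,
    signal_terms: list[str],
    recurrent_ids: list[str],
    n_signal_genes: int = 10,
    shift_sd: float = 2.0,
    seed: int = 0,
    signal_genes: dict[str, list[str]] | None = None,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Shift recurrent samples on a subset of each signal term's genes.

    The shift is ``shift_sd`` per-gene standard deviations (computed across
    all samples), applied additively on the matrix's scale. Null terms are
    untouched unless they happen to share planted genes. Signal genes are
    drawn at random within each term unless ``signal_genes`` pins them
    explicitly (term id -> gene list, each a subset of the term).
    """
    rng = np.random.default_rng(seed)
    values = matrix.values.copy()
    truth = SyntheticTruth(
        seed=seed, params={"shift_sd": shift_sd, "n_signal_genes": n_signal_genes}
    )
    rec = [s for s in recurrent_ids if s in values.columns]
    for term_id in signal_terms:
        term = collection.get(term_id)
        present = [g for g in term.genes if g in values.index]
        if signal_genes is not None:
            outside = set(signal_genes[term_id]) - set(term.genes)
            if outside:
                raise ValueError(f"signal genes outside term {term_id}: {sorted(outside)}")
            chosen = [g for g in signal_genes[term_id] if g in present]
        else:
            chosen = list(rng.choice(present, size=min(n_signal_genes, len(present)), replace=False))
        for g in chosen:
            sd = values.loc[g].std(ddof=0)
            if sd == 0:
                sd = 1.0
            values.loc[g, rec] = values.loc[g, rec] + shift_sd * sd
        truth.signal_terms.append(term_id)
        truth.signal_genes[term_id] = sorted(chosen)
    shifted = ExpressionMatrix(values.clip(lower=0) if matrix.scale_tag == "raw_counts" else values,
                               matrix.scale_tag)
    return shifted, truth


def simulate_recovery_benchmark(
    seed: int,
    n_planted: int = 20,
    n_primary: int = 50,
    n_recurrent: int = 16,
    shift_sd: float = 2.0,
    filler_multiple: float = 1.5,
    n_null_terms: int = 3,
) -> tuple[ExpressionMatrix, pd.DataFrame, list, list[str]]:
    """Planted-signature benchmark for the classifier + consensus stages.

    Six curated terms: three signal terms and ``n_null_terms`` pure-noise
    terms. Each planted gene is a member of two of the three signal terms, as
    a minority among term-specific filler genes — per-sample standardization
    spreads any shift across a term's z-scores, so a planted majority would
    hand the contrast to the fillers. Planted genes are shifted by
    ``shift_sd`` standard deviations in recurrent samples; their two-term
    membership gives them discriminant score 2 against 1 for any filler the
    consensus happens to keep.

    Returns (expression, metadata, curated term selections, planted genes).
    """
    from itertools import combinations

    from .enrichment import TermSelection

    rng = np.random.default_rng(seed)
    prim = [f"P{i:03d}" for i in range(n_primary)]
    rec = [f"R{i:03d}" for i in range(n_recurrent)]
    planted = [f"sig{i:02d}" for i in range(n_planted)]
    assign = list(combinations(range(3), 2))
    members: dict[int, list[str]] = {t: [] for t in range(3)}
    for i, g in enumerate(planted):
        for t in assign[i % 3]:
            members[t].append(g)
    terms, genes = [], list(planted)
    for t in range(3):
        m = members[t]
        fillers = [f"fill{t}_{i:02d}" for i in range(int(filler_multiple * len(m)))]
        genes += fillers
        terms.append(
            TermSelection(f"S{t}", f"signal term {t}", "pathway" if t < 2 else "go_bp",
                          tuple(m + fillers))
        )
    for t in range(n_null_terms):
        noise = [f"noise{t}_{i:02d}" for i in range(30)]
        genes += noise
        terms.append(
            TermSelection(f"N{t}", f"null term {t}", "pathway" if t < 2 else "go_bp",
                          tuple(noise))
        )
    vals = rng.normal(5.0, 1.0, size=(len(genes), n_primary + n_recurrent))
    df = pd.DataFrame(vals, index=genes, columns=prim + rec)
    df.loc[planted, rec] += shift_sd
    meta = pd.DataFrame(
        {
            "sample_id": prim + rec,
            "patient_id": prim + rec,
            "tissue_class": ["primary"] * n_primary + ["recurrent"] * n_recurrent,
            "cohort": "augmentation",
            "histology_label": "hcc",
        }
    )
    return ExpressionMatrix(df, "normalized"), meta, terms, planted


# ---------------------------------------------------------------------------
# immune signature and mixtures
# ---------------------------------------------------------------------------

def simulate_signature_matrix(
    n_cell_types: int = 22,
    markers_per_type: int = 15,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic immune reference: each cell type gets a block of marker genes
    with elevated expression over a shared low baseline."""
    rng = np.random.default_rng(seed)
    n_genes = n_cell_types * markers_per_type
    genes = [f"IMM{i:04d}" for i in range(n_genes)]
    types = [f"celltype_{i:02d}" for i in range(n_cell_types)]
    base = rng.uniform(1.0, 10.0, size=(n_genes, n_cell_types))
    for t in range(n_cell_types):
        block = slice(t * markers_per_type, (t + 1) * markers_per_type)
        base[block, t] += rng.uniform(80.0, 150.0, size=markers_per_type)
    return pd.DataFrame(base, index=genes, columns=types)


def simulate_mixtures(
    signature: pd.DataFrame,
    n_samples: int,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bulk mixtures with Dirichlet ground-truth fractions.

    Gaussian noise of ``noise_sd`` (relative to each mixture's mean level) is
    added and clipped at zero. Returns (mixtures genes x samples, true
    fractions samples x cell types).
    """
    rng = np.random.default_rng(seed)
    k = signature.shape[1]
    fracs = rng.dirichlet(np.ones(k), size=n_samples)
    mix = signature.to_numpy() @ fracs.T
    if noise_sd > 0:
        mix = mix + rng.normal(0.0, noise_sd * mix.mean(), size=mix.shape)
        mix = np.clip(mix, 0.0, None)
    samples = [f"MIX{i:03d}" for i in range(n_samples)]
    return (
        pd.DataFrame(mix, index=signature.index, columns=samples),
        pd.DataFrame(fracs, index=samples, columns=signature.columns),
    )


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def simulate_survival(
    n_per_group: dict[str, int],
    hazard_ratio: float = 2.0,
    median_unaltered_months: float = 30.0,
    censor_frac: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential event times with rate ratio ``hazard_ratio`` for the
    altered group, under independent uniform censoring.

    ``censor_frac`` is the expected fraction censored; ``censor_frac = 1``
    censors every subject.
    """
    if hazard_ratio <= 0:
        raise ValueError("hazard_ratio must be > 0")
    rng = np.random.default_rng(seed)
    base_rate = np.log(2.0) / median_unaltered_months
    rows = []
    for group, n in n_per_group.items():
        rate = base_rate * (hazard_ratio if group == "altered" else 1.0)
        event_times = rng.exponential(1.0 / rate, size=n)
        if censor_frac >= 1.0:
            times, events = event_times, np.zeros(n, dtype=int)
        elif censor_frac <= 0.0:
            times, events = event_times, np.ones(n, dtype=int)
        else:
            # uniform censoring horizon calibrated so ~censor_frac are censored
            horizon = np.quantile(event_times, 1.0 - censor_frac) * 2.0
            censor_times = rng.uniform(0, horizon, size=n)
            events = (event_times <= censor_times).astype(int)
            times = np.minimum(event_times, censor_times)
        for i in range(n):
            rows.append(
                {
                    "sample": f"{group}_{i:03d}",
                    "time": max(float(times[i]), 1e-6),
                    "event": int(events[i]),
                    "group": group,
                }
            )
    return pd.DataFrame(rows)
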