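"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator plants:

* four methylation epigenotypes with block-structured marker classes
  (high / intermediate / common / normally methylated), at the published
  per-class, per-epigenotype group means;
* normal mucosa drawn at the NME means, so normals cluster with the
  lowest-methylation group;
* FAP-IME methylation attenuation — FAP IME samples draw intermediate and
  common markers at reduced means (0.35 -> 0.22 and 0.48 -> 0.34);
* a KRAS-mutation/epigenotype association among FAP samples (default planted
  contingency [[5, 0], [4, 13]] for IME/NME x mutant/wildtype), realised as
  pyrosequencing allele-quantification records;
* one extreme FAP outlier sample (inverted beta profile) to exercise
  smallest-cluster outlier flagging;
* frozen/FFPE pairs with a planted discordant probe fraction, emulating the
  concordance scatter (most probes near y = x, a minority shifted outside
  the +/-0.1 band).

Every draw flows from one seed; same (seed, config) means identical bytes.
Noise is truncated-normal per value (default SD 0.05; clipping mass is
recorded and stays under 1% at the default means), with a moment-matched
beta-distribution mode for strictly bounded draws.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import BetaMatrix, InputError, write_annotation, write_beta_matrix, write_metadata
from .mutations import AlleleQuantification

__all__ = [
    "CohortConfig",
    "fast_cohort_config",
    "SyntheticTruth",
    "SyntheticCohort",
    "generate_cohort",
    "generate_ffpe_pairs",
    "generate_probe_windows",
    "DEFAULT_CLASS_ME_MEANS",
    "DEFAULT_CLASS_SIZES",
    "DEFAULT_COHORT_SIZES",
]

_MES = ("HME", "IME", "LME", "NME")

# Per-marker-class, per-epigenotype group mean beta (sporadic neoplasm scale).
# high/intermediate/common rows carry the published sporadic group means; the
# normally-methylated row keeps all four means >= 0.2 with enough spread to
# pass the SD > 0.10 variance filter (as such genes did in real cohorts).
DEFAULT_CLASS_ME_MEANS = pd.DataFrame(
    {
        "HME": [0.49, 0.56, 0.55, 0.70],
        "IME": [0.17, 0.35, 0.48, 0.52],
        "LME": [0.15, 0.15, 0.34, 0.35],
        "NME": [0.11, 0.10, 0.11, 0.45],
    },
    index=["high", "intermediate", "common", "normal"],
)

# Filler genes emulate the variable-but-unclassified majority of clustering
# probes: each filler gene draws a methylated/unmethylated pattern over the
# four epigenotypes that is NOT one of the four nested marker patterns, with
# unmethylated means from FILLER_LOW and methylated means from FILLER_HIGH.
# These genes stay "unclassified" in marker extraction yet pass the variance
# filter and decorrelate the epigenotypes under correlation distance, which
# an overall-level difference alone cannot do.
_NESTED_PATTERNS = {(1, 0, 0, 0), (1, 1, 0, 0), (1, 1, 1, 0), (1, 1, 1, 1)}
FILLER_PATTERNS = tuple(
    (a, b, c, d)
    for a in (0, 1) for b in (0, 1) for c in (0, 1) for d in (0, 1)
    if (a, b, c, d) not in _NESTED_PATTERNS)
FILLER_LOW = (0.09, 0.14)
FILLER_HIGH = (0.30, 0.55)

# FAP IME samples draw these classes at attenuated means.
DEFAULT_FAP_IME_MEANS = {"intermediate": 0.22, "common": 0.34}

DEFAULT_CLASS_SIZES = {"high": 186, "intermediate": 69, "common": 149,
                       "normal": 41, "filler": 556}

DEFAULT_COHORT_SIZES: dict[str, dict[str, int]] = {
    "sporadic_CRC": {"HME": 62, "IME": 90, "LME": 135, "NME": 10},
    "sporadic_adenoma": {"HME": 5, "IME": 25, "LME": 14, "NME": 1},
    "normal": {"NME": 37},
    "FAP": {"IME": 5, "NME": 17},
}

# Planted FAP contingency tables (rows IME/NME): KRAS mutant/wildtype,
# proximal/distal location, adenoma/cancer histology.
DEFAULT_KRAS_TABLE = ((5, 0), (4, 13))
DEFAULT_LOCATION_TABLE = ((5, 0), (4, 13))
DEFAULT_HISTOLOGY_TABLE = ((3, 2), (13, 4))


@dataclasses.dataclass
class CohortConfig:
    """Generator parameters; the defaults define the emulated cohort conditions."""

    class_sizes: dict[str, int] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_CLASS_SIZES))
    class_me_means: pd.DataFrame = dataclasses.field(
        default_factory=lambda: DEFAULT_CLASS_ME_MEANS.copy())
    fap_ime_means: dict[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_FAP_IME_MEANS))
    cohort_sizes: dict[str, dict[str, int]] = dataclasses.field(
        default_factory=lambda: {c: dict(v) for c, v in DEFAULT_COHORT_SIZES.items()})
    n_fap_outliers: int = 1
    noise_sd: float = 0.05
    noise_model: str = "truncnorm"  # or "beta"
    filler_low: tuple[float, float] = FILLER_LOW
    filler_high: tuple[float, float] = FILLER_HIGH
    kras_table: tuple[tuple[int, int], tuple[int, int]] = DEFAULT_KRAS_TABLE
    sd_threshold: float = 0.10

    def __post_init__(self):
        means = self.class_me_means
        if ((means < 0) | (means > 1)).any().any():
            raise InputError("class x epigenotype mean beta values must lie in [0, 1]")
        if self.noise_sd < 0:
            raise InputError("noise SD must be >= 0")
        for cls, size in self.class_sizes.items():
            if size < 0:
                raise InputError(f"negative class size for {cls!r}")
        unknown = set(self.class_sizes) - set(means.index) - {"filler"}
        if unknown:
            raise InputError(f"class sizes for classes without means: {sorted(unknown)}")
        if not (0 <= self.filler_low[0] <= self.filler_low[1] < 0.2
                <= self.filler_high[0] <= self.filler_high[1] <= 1):
            raise InputError("filler mean ranges must straddle the 0.2 threshold")
        kras = np.asarray(self.kras_table)
        fap = self.cohort_sizes.get("FAP", {})
        if kras[0].sum() > fap.get("IME", 0) or kras[1].sum() > fap.get("NME", 0):
            raise InputError("planted KRAS table larger than the FAP epigenotype groups")

    def scaled(self, sample_factor: float, gene_factor: float) -> "CohortConfig":
        """Proportionally smaller cohort (nonzero groups keep at least 1 member)."""

        def shrink(n: int, f: float) -> int:
            return 0 if n == 0 else max(1, int(round(n * f)))

        sizes = {c: {me: shrink(n, sample_factor) for me, n in groups.items()}
                 for c, groups in self.cohort_sizes.items()}
        classes = {cls: shrink(n, gene_factor) for cls, n in self.class_sizes.items()}
        fap = sizes.get("FAP", {})
        kras = np.asarray(self.kras_table, dtype=float)
        scaled_kras = []
        for row, total in zip(kras, (fap.get("IME", 0), fap.get("NME", 0))):
            frac = row / row.sum() if row.sum() else row
            mutant = int(round(frac[0] * total))
            scaled_kras.append((mutant, total - mutant))
        return dataclasses.replace(
            self, class_sizes=classes, cohort_sizes=sizes,
            kras_table=(tuple(scaled_kras[0]), tuple(scaled_kras[1])))


def fast_cohort_config() -> CohortConfig:
    """A ~100-sample x ~300-gene cohort for quick tests and demos.

    Proportional 0.25x / 0.3x scaling of the full-size defaults, except that
    the smallest sporadic group (NME) keeps 8 samples: a 3-sample group's mean
    beta (SE ~0.03 at the default noise) is too unstable for 0.2-threshold
    classification; realistic cohorts of this design keep n ~ 10 in their
    smallest group.
    """
    config = CohortConfig().scaled(0.25, 0.3)
    sizes = {c: dict(v) for c, v in config.cohort_sizes.items()}
    sizes["sporadic_CRC"]["NME"] = 8
    return dataclasses.replace(config, cohort_sizes=sizes)


@dataclasses.dataclass
class SyntheticTruth:
    """Planted labels, memberships and effect parameters for recovery tests."""

    sample_labels: pd.Series            # planted ME per sample ("outlier" for the outlier)
    sample_cohorts: pd.Series
    gene_classes: pd.Series             # planted marker class per gene
    gene_me_means: pd.DataFrame         # noise-free per-gene x epigenotype means
    config: CohortConfig
    seed: int
    truncation_fraction: float
    expected_variable_genes: frozenset[str]  # genes whose noise-free SD exceeds sd_threshold
    kras_status: pd.Series


@dataclasses.dataclass
class SyntheticCohort:
    beta: BetaMatrix
    annotation: pd.DataFrame
    metadata: pd.DataFrame
    truth: SyntheticTruth
    allele_quantifications: list[AlleleQuantification]

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_beta_matrix(self.beta, out / "beta.tsv")
        write_annotation(self.annotation, out / "annotation.tsv")
        write_metadata(self.metadata, out / "metadata.tsv")
        truth = pd.DataFrame({"planted_epigenotype": self.truth.sample_labels,
                              "cohort": self.truth.sample_cohorts})
        truth.index.name = "sample_id"
        truth.to_csv(out / "truth_samples.tsv", sep="\t")
        genes = self.truth.gene_classes.rename("planted_class").to_frame()
        genes.index.name = "gene"
        genes.to_csv(out / "truth_genes.tsv", sep="\t")
        aq = pd.DataFrame([dataclasses.asdict(a) for a in self.allele_quantifications])
        aq.to_csv(out / "allele_quantification.tsv", sep="\t", index=False)


def _noise(rng: np.random.Generator, means: np.ndarray, sd: float,
           model: str) -> tuple[np.ndarray, int]:
    """Draw beta values around `means`; returns (values, number of clipped draws)."""
    if sd == 0:
        return means.copy(), 0
    if model == "truncnorm":
        raw = means + rng.normal(0.0, sd, size=means.shape)
        clipped = int(np.sum((raw < 0) | (raw > 1)))
        return np.clip(raw, 0.0, 1.0), clipped
    if model == "beta":
        var = sd ** 2
        m = np.clip(means, 1e-6, 1 - 1e-6)
        nu = m * (1 - m) / var - 1
        if np.any(nu <= 0):
            raise InputError("beta noise model: SD too large for a mean this extreme")
        return rng.beta(m * nu, (1 - m) * nu, size=means.shape), 0
    raise InputError(f"unknown noise model {model!r}")


def generate_cohort(config: CohortConfig | None = None,
                    seed: int = 0) -> SyntheticCohort:
    """Generate a full synthetic cohort (beta matrix, annotation, metadata, truth).

    Deterministic for fixed (config, seed).  With ``noise_sd=0`` every group's
    empirical mean equals the configured mean exactly.
    """
    config = config if config is not None else CohortConfig()
    rng = np.random.default_rng(seed)

    # genes, one promoter probe each
    gene_classes: dict[str, str] = {}
    i = 0
    class_order = [c for c in list(config.class_me_means.index) + ["filler"]
                   if c in config.class_sizes]
    for cls in class_order:
        for _ in range(config.class_sizes.get(cls, 0)):
            i += 1
            gene_classes[f"G{i:05d}"] = cls
    genes = list(gene_classes)
    if not genes:
        raise InputError("no genes configured")
    gene_class_series = pd.Series(gene_classes, name="planted_class")

    # samples
    rows = []
    for cohort in sorted(config.cohort_sizes):
        for me in _MES:
            for j in range(config.cohort_sizes[cohort].get(me, 0)):
                rows.append((f"{cohort}_{me}_{j + 1:03d}", cohort, me))
    for j in range(config.n_fap_outliers):
        rows.append((f"FAP_outlier_{j + 1:03d}", "FAP", "outlier"))
    if not rows:
        raise InputError("no samples configured")
    sample_ids = [r[0] for r in rows]
    sample_cohorts = pd.Series({r[0]: r[1] for r in rows}, name="cohort")
    sample_labels = pd.Series({r[0]: r[2] for r in rows}, name="planted_epigenotype")

    # per-gene x epigenotype noise-free means: marker classes at their class
    # means, fillers at per-gene random non-nested patterns
    gene_me_means = pd.DataFrame(0.0, index=genes, columns=list(_MES))
    class_of_gene = gene_class_series.to_numpy()
    for cls in config.class_me_means.index:
        mask = class_of_gene == cls
        gene_me_means.loc[mask, :] = config.class_me_means.loc[cls, list(_MES)].to_numpy()
    filler_mask = class_of_gene == "filler"
    n_filler = int(filler_mask.sum())
    if n_filler:
        pattern_idx = rng.integers(0, len(FILLER_PATTERNS), size=n_filler)
        bits = np.array(FILLER_PATTERNS)[pattern_idx].astype(bool)
        lows = rng.uniform(*config.filler_low, size=(n_filler, len(_MES)))
        highs = rng.uniform(*config.filler_high, size=(n_filler, len(_MES)))
        gene_me_means.loc[filler_mask, :] = np.round(np.where(bits, highs, lows), 4)

    # noise-free mean matrix (genes x samples)
    mean_matrix = np.empty((len(genes), len(sample_ids)))
    fap_ime_profile = gene_me_means["IME"].copy()
    for cls, attenuated in config.fap_ime_means.items():
        fap_ime_profile[class_of_gene == cls] = attenuated
    for col, (sid, cohort, me) in enumerate(rows):
        if me == "outlier":
            profile = 1.0 - gene_me_means["NME"]
        elif cohort == "FAP" and me == "IME":
            profile = fap_ime_profile
        else:
            profile = gene_me_means[me]
        mean_matrix[:, col] = profile.to_numpy()

    values, clipped = _noise(rng, mean_matrix, config.noise_sd, config.noise_model)
    beta = BetaMatrix(pd.DataFrame(values, index=genes, columns=sample_ids))

    # annotation: one probe per gene at a plausible promoter coordinate
    positions = 10_000 + 2_000 * np.arange(len(genes))
    annotation = pd.DataFrame({
        "chromosome": "chr1",
        "position": positions + rng.integers(-200, 201, size=len(genes)),
        "gene": genes,
        "tss_position": positions,
        "strand": "+",
        "cpg_score": np.round(rng.uniform(0.55, 1.2, size=len(genes)), 4),
    }, index=pd.Index(genes, name="probe_id"))

    # noise-free SD decides which genes the variance filter is expected to keep
    noise_free_sd = pd.DataFrame(mean_matrix, index=genes).std(axis=1, ddof=1)
    expected_variable = frozenset(noise_free_sd.index[noise_free_sd > config.sd_threshold])

    metadata, kras_status, aqs = _fap_phenotypes(config, rows, rng)

    truth = SyntheticTruth(
        sample_labels=sample_labels, sample_cohorts=sample_cohorts,
        gene_classes=gene_class_series, gene_me_means=gene_me_means,
        config=config, seed=seed,
        truncation_fraction=clipped / values.size,
        expected_variable_genes=expected_variable, kras_status=kras_status)
    return SyntheticCohort(beta=beta, annotation=annotation, metadata=metadata,
                           truth=truth, allele_quantifications=aqs)


def _fap_phenotypes(config: CohortConfig, rows: list[tuple[str, str, str]],
                    rng: np.random.Generator,
                    ) -> tuple[pd.DataFrame, pd.Series, list[AlleleQuantification]]:
    """Sample metadata, planted KRAS truth and pyrosequencing records."""
    kras_plan: dict[str, str] = {}
    location_plan: dict[str, str] = {}
    histology_plan: dict[str, str] = {}
    for row_idx, me in enumerate(("IME", "NME")):
        members = [sid for sid, cohort, lab in rows if cohort == "FAP" and lab == me]
        n_mut = config.kras_table[row_idx][0]
        for j, sid in enumerate(members):
            kras_plan[sid] = "mutant" if j < n_mut else "wildtype"
            location_plan[sid] = ("proximal"
                                  if j < DEFAULT_LOCATION_TABLE[row_idx][0] else "distal")
            histology_plan[sid] = ("adenoma"
                                   if j < DEFAULT_HISTOLOGY_TABLE[row_idx][0] else "cancer")

    meta_rows, kras_truth, aqs = [], {}, []
    ssa_budget = 3
    for sid, cohort, me in rows:
        if cohort == "FAP":
            if me == "outlier":
                status, location, histology = "unknown", "unknown", "adenoma"
            else:
                status = kras_plan[sid]
                location = location_plan[sid]
                histology = histology_plan[sid]
            preparation = "FFPE"
        elif cohort == "normal":
            status, location, histology, preparation = "unknown", "unknown", "normal", "frozen"
        else:
            status, location, preparation = "unknown", "unknown", "frozen"
            if cohort == "sporadic_adenoma":
                if me == "HME" and ssa_budget > 0:
                    histology, ssa_budget = "SSA", ssa_budget - 1
                else:
                    histology = "adenoma"
            else:
                histology = "cancer"
        meta_rows.append({"sample_id": sid, "cohort": cohort, "preparation": preparation,
                          "location": location, "histology": histology,
                          "kras_status": status, "braf_status":
                              "wildtype" if cohort == "FAP" and me != "outlier" else "unknown"})
        kras_truth[sid] = status

        if cohort == "FAP":
            content = 30.0 if me == "outlier" else float(np.round(rng.uniform(45, 90), 1))
            mutant_locus = rng.choice(["KRAS_34", "KRAS_35", "KRAS_37", "KRAS_38"])
            for locus in ("BRAF_1799", "KRAS_34", "KRAS_35", "KRAS_37", "KRAS_38"):
                if status == "mutant" and locus == mutant_locus:
                    frac = float(np.round(rng.uniform(30, 70), 1))
                else:
                    frac = float(np.round(rng.uniform(0, 8), 1))
                aqs.append(AlleleQuantification(sample_id=sid, locus=locus,
                                                fraction_percent=frac,
                                                tumor_content_percent=content))

    metadata = pd.DataFrame(meta_rows).set_index("sample_id")
    return metadata, pd.Series(kras_truth, name="kras_status"), aqs


def generate_ffpe_pairs(base: pd.DataFrame,
                        perturbation_sd: float = 0.02,
                        discordant_fraction: float = 0.2,
                        discordant_shift: float = 0.3,
                        delta_threshold: float = 0.1,
                        seed: int = 0,
                        ) -> tuple[list[tuple[pd.Series, pd.Series]], list[frozenset[str]]]:
    """Frozen/FFPE pairs from per-pair base profiles (columns of ``base``).

    The frozen member is the base profile; the FFPE member adds small noise to
    concordant probes and an additional shift (directed away from the nearer
    [0, 1] boundary) to a planted discordant fraction.  Returns the pairs and
    the planted per-pair concordant probe sets.
    """
    if perturbation_sd < 0:
        raise InputError("perturbation SD must be >= 0")
    if not 0 <= discordant_fraction <= 1:
        raise InputError("discordant fraction must lie in [0, 1]")
    if discordant_shift <= delta_threshold:
        raise InputError("discordant shift must exceed the concordance threshold "
                         "(otherwise discordance is undetectable)")
    rng = np.random.default_rng(seed)
    pairs: list[tuple[pd.Series, pd.Series]] = []
    planted_concordant: list[frozenset[str]] = []
    probes = base.index
    n_discordant = int(round(discordant_fraction * len(probes)))
    for col in base.columns:
        frozen = base[col].astype(float)
        ffpe = frozen + rng.normal(0.0, perturbation_sd, size=len(probes))
        discordant_idx = rng.choice(len(probes), size=n_discordant, replace=False)
        direction = np.where(frozen.to_numpy()[discordant_idx] <= 0.5, 1.0, -1.0)
        ffpe.iloc[discordant_idx] += direction * discordant_shift
        ffpe = ffpe.clip(0.0, 1.0)
        pairs.append((frozen.rename(f"{col}_frozen"), ffpe.rename(f"{col}_FFPE")))
        planted_concordant.append(frozenset(probes.delete(discordant_idx)))
    return pairs, planted_concordant


def generate_probe_windows(targets: Mapping[str, float] | Sequence[float],
                           c_count: int = 125,
                           g_count: int = 125,
                           length: int = 500,
                           tolerance: float = 0.02) -> dict[str, str]:
    """Construct 500-bp windows whose counted CpG o/e ratio hits each target.

    Places ``n`` CG dinucleotides (``n = round(target * c_count * g_count /
    length)``) among fixed C/G content, with all remaining C and G bases
    followed by A so no extra CG can form.  Raises when the achievable grid
    point is farther than ``tolerance`` from the target.
    """
    if not isinstance(targets, Mapping):
        targets = {f"W{i + 1:04d}": t for i, t in enumerate(targets)}
    windows: dict[str, str] = {}
    expected = c_count * g_count / length
    for name, target in targets.items():
        if not 0 <= target <= 2:
            raise InputError(f"target CpG score {target} outside [0, 2]")
        n = int(round(target * expected))
        pad = length - (3 * n + 2 * (c_count - n) + 2 * (g_count - n))
        if n > min(c_count, g_count) or pad < 0:
            raise InputError(f"target {target} unreachable with C={c_count}, G={g_count}")
        achieved = n / expected
        if abs(achieved - target) > tolerance:
            raise InputError(
                f"target {target} unreachable within {tolerance} "
                f"(nearest grid point {achieved:.4f})")
        seq = "CGA" * n + "CA" * (c_count - n) + "GA" * (g_count - n) + "T" * pad
        windows[name] = seq
    return windows
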