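"""Synthetic expression corpora, gold standards, query samples, and survival cohorts.

The generator plants class-specific TF hubs whose targets are co-elevated in
samples of that class, on top of a pool of background genes, using
multiplicative log-normal noise on a positive baseline so that matrices stay
strictly positive (as per-array total normalization assumes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a planted-hub multi-class expression corpus.

    ``hub_effect`` is the fold-change applied to a class's TFs and their
    targets in samples of that class; ``noise_sd`` is the standard deviation
    of the log-scale noise; ``decoy_pairs`` gold-standard pairs are drawn
    among background genes with no planted co-regulation.
    """

    n_classes: int = 3
    n_tfs_per_class: int = 2
    targets_per_tf: int = 5
    n_background_genes: int = 200
    samples_per_class: int = 20
    hub_effect: float = 4.0
    noise_sd: float = 0.5
    decoy_pairs: int = 20
    baseline: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_classes",
            "n_tfs_per_class",
            "targets_per_tf",
            "n_background_genes",
            "samples_per_class",
            "decoy_pairs",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.hub_effect < 1:
            raise ValueError(f"hub_effect must be >= 1, got {self.hub_effect}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.baseline <= 0:
            raise ValueError(f"baseline must be > 0, got {self.baseline}")

    @property
    def n_planted_genes(self) -> int:
        return self.n_classes * self.n_tfs_per_class * (1 + self.targets_per_tf)

    @property
    def n_genes(self) -> int:
        return self.n_planted_genes + self.n_background_genes

    @property
    def n_samples(self) -> int:
        return self.n_classes * self.samples_per_class


@dataclass
class GroundTruth:
    """Planted structure of a simulated corpus.

    Every TF belongs to exactly one class; TF/target sets are disjoint from
    background genes; baselines are strictly positive.
    """

    class_tfs: dict[str, list[str]]
    tf_targets: dict[str, list[str]]
    background_genes: list[str]
    baselines: dict[str, float]

    @property
    def classes(self) -> list[str]:
        return list(self.class_tfs)

    def class_genes(self, cls: str) -> list[str]:
        """All planted genes of a class: its TFs plus their targets."""
        genes: list[str] = []
        for tf in self.class_tfs[cls]:
            genes.append(tf)
            genes.extend(self.tf_targets[tf])
        return genes

    @property
    def genes(self) -> list[str]:
        out: list[str] = []
        for cls in self.class_tfs:
            out.extend(self.class_genes(cls))
        out.extend(self.background_genes)
        return out

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "class_tfs": self.class_tfs,
                    "tf_targets": self.tf_targets,
                    "background_genes": self.background_genes,
                    "baselines": self.baselines,
                },
                fh,
            )

    @classmethod
    def from_yaml(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(
            class_tfs=d["class_tfs"],
            tf_targets=d["tf_targets"],
            background_genes=d["background_genes"],
            baselines=d["baselines"],
        )


@dataclass(frozen=True)
class SurvivalSimConfig:
    """Parameters of a simulated survival cohort with a step hazard effect.

    Expression is log-normal; patients with expression above ``true_cutoff``
    have hazard ``h0 * exp(beta)``, the rest ``h0``. A fraction
    ``censor_rate`` of patients is independently right-censored uniformly
    before their event time.
    """

    n_patients: int = 100
    beta: float = 1.0
    censor_rate: float = 0.0
    true_cutoff: float = 1.0
    h0: float = 0.1
    expr_log_mean: float = 0.0
    expr_log_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError(f"n_patients must be >= 2, got {self.n_patients}")
        if not 0 <= self.censor_rate < 1:
            raise ValueError(f"censor_rate must be in [0, 1), got {self.censor_rate}")
        if self.h0 <= 0:
            raise ValueError(f"h0 must be > 0, got {self.h0}")


def _gene_names(config: SimulationConfig) -> GroundTruth:
    class_tfs: dict[str, list[str]] = {}
    tf_targets: dict[str, list[str]] = {}
    for c in range(config.n_classes):
        cls = f"class{c + 1:02d}"
        tfs = []
        for i in range(config.n_tfs_per_class):
            tf = f"TF{c + 1:02d}_{i + 1}"
            tfs.append(tf)
            tf_targets[tf] = [
                f"TG{c + 1:02d}_{i + 1}_{j + 1}" for j in range(config.targets_per_tf)
            ]
        class_tfs[cls] = tfs
    background = [f"BG{k + 1:04d}" for k in range(config.n_background_genes)]
    truth = GroundTruth(
        class_tfs=class_tfs,
        tf_targets=tf_targets,
        background_genes=background,
        baselines={},
    )
    truth.baselines = {g: float(config.baseline) for g in truth.genes}
    return truth


def generate_gold_standard(
    config: SimulationConfig,
) -> tuple[list[tuple[str, str]], GroundTruth]:
    """Emit the gold-standard TF->target pair list and the planted truth.

    The gold standard holds every planted class-TF->target pair plus exactly
    ``config.decoy_pairs`` pairs among background genes that carry no planted
    co-regulation. Deterministic under ``config.seed``.
    """
    truth = _gene_names(config)
    pairs: list[tuple[str, str]] = []
    for cls in truth.classes:
        for tf in truth.class_tfs[cls]:
            for tg in truth.tf_targets[tf]:
                pairs.append((tf, tg))

    if config.decoy_pairs > 0:
        if config.n_background_genes < 2:
            raise ValueError("decoy pairs require at least 2 background genes")
        rng = np.random.default_rng([config.seed, 0])
        bg = truth.background_genes
        seen: set[tuple[str, str]] = set()
        while len(seen) < config.decoy_pairs:
            i, j = rng.choice(len(bg), size=2, replace=False)
            seen.add((bg[i], bg[j]))
        pairs.extend(sorted(seen))
    return pairs, truth


def _effect_matrix(
    config: SimulationConfig, truth: GroundTruth, class_of_col: list[str]
) -> np.ndarray:
    genes = truth.genes
    gene_idx = {g: i for i, g in enumerate(genes)}
    eff = np.ones((len(genes), len(class_of_col)))
    for j, cls in enumerate(class_of_col):
        if cls is None:
            continue
        for g in truth.class_genes(cls):
            eff[gene_idx[g], j] = config.hub_effect
    return eff


def _intensities(
    config: SimulationConfig,
    truth: GroundTruth,
    eff: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    base = np.array([truth.baselines[g] for g in truth.genes])[:, None]
    noise = rng.normal(0.0, config.noise_sd, size=eff.shape)
    return base * eff * np.exp(noise)


def simulate_corpus(
    config: SimulationConfig, truth: GroundTruth
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the multi-class training corpus.

    Returns a sample table (sample_id, file_name, description) and a
    gene-by-sample expression matrix. In samples of class c, the TFs of c
    and their targets have expected intensity ``baseline * hub_effect``; all
    other genes sit at baseline. Intensities are
    ``baseline * effect * exp(N(0, noise_sd^2))`` and strictly positive.
    """
    rng = np.random.default_rng([config.seed, 1])
    sample_ids: list[str] = []
    class_of_col: list[str] = []
    for cls in truth.classes:
        for s in range(config.samples_per_class):
            sample_ids.append(f"{cls}_s{s + 1:02d}")
            class_of_col.append(cls)
    eff = _effect_matrix(config, truth, class_of_col)
    mat = _intensities(config, truth, eff, rng)
    expr = pd.DataFrame(mat, index=truth.genes, columns=sample_ids)
    table = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "file_name": [f"{s}.CEL" for s in sample_ids],
            "description": class_of_col,
        }
    )
    return table, expr


def simulate_query(
    config: SimulationConfig,
    truth: GroundTruth,
    target_class: str,
    attenuation: float,
    n: int,
    seed: int,
    silenced_tfs: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Simulate query samples partially establishing one class's program.

    A random fraction ``attenuation`` of the class's planted genes receives
    the hub effect; the rest stay at baseline. ``attenuation=1`` reproduces
    the training generative law for the class; ``attenuation=0`` the
    background law. ``silenced_tfs`` forces the named TFs and all their
    targets to baseline regardless of the attenuation draw.
    """
    if target_class not in truth.class_tfs:
        raise KeyError(f"unknown class: {target_class!r}")
    if not 0 <= attenuation <= 1:
        raise ValueError(f"attenuation must be in [0, 1], got {attenuation}")
    rng = np.random.default_rng([seed, 2])
    class_genes = truth.class_genes(target_class)
    k = int(round(attenuation * len(class_genes)))
    chosen = set(
        np.array(class_genes)[rng.choice(len(class_genes), size=k, replace=False)]
        if k > 0
        else []
    )
    for tf in silenced_tfs:
        if tf not in truth.tf_targets:
            raise KeyError(f"unknown TF: {tf!r}")
        chosen.discard(tf)
        chosen.difference_update(truth.tf_targets[tf])

    genes = truth.genes
    gene_idx = {g: i for i, g in enumerate(genes)}
    eff = np.ones((len(genes), n))
    for g in chosen:
        eff[gene_idx[g], :] = config.hub_effect
    mat = _intensities(config, truth, eff, rng)
    cols = [f"query_{target_class}_q{j + 1:02d}" for j in range(n)]
    return pd.DataFrame(mat, index=genes, columns=cols)


def simulate_survival(config: SurvivalSimConfig) -> pd.DataFrame:
    """Simulate a survival cohort with a planted binary-expression effect.

    Event times are exponential with hazard
    ``h0 * exp(beta * 1{expression > true_cutoff})``; a random fraction
    ``censor_rate`` of patients is censored uniformly on (0, T).
    Returns columns: patient_id, time, event, expression.
    """
    rng = np.random.default_rng([config.seed, 3])
    expr = rng.lognormal(
        mean=config.expr_log_mean, sigma=config.expr_log_sd, size=config.n_patients
    )
    high = expr > config.true_cutoff
    hazard = config.h0 * np.exp(config.beta * high.astype(float))
    t_event = rng.exponential(1.0 / hazard)
    censored = rng.random(config.n_patients) < config.censor_rate
    t_obs = np.where(censored, rng.uniform(0.0, t_event), t_event)
    # uniform(0, T) can hit 0.0 exactly in principle; keep times positive
    t_obs = np.maximum(t_obs, np.finfo(float).tiny)
    return pd.DataFrame(
        {
            "patient_id": [f"P{i + 1:04d}" for i in range(config.n_patients)],
            "time": t_obs,
            "event": (~censored).astype(int),
            "expression": expr,
        }
    )


def write_gold_standard(pairs: list[tuple[str, str]], path) -> None:
    pd.DataFrame(pairs, columns=["tf", "target"]).to_csv(path, sep="\t", index=False)


def read_gold_standard(path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return list(df[["tf", "target"]].itertuples(index=False, name=None))


def config_to_dict(config) -> dict:
    return asdict(config)
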