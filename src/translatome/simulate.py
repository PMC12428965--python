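"""Synthetic paired total/polysome cold-stress experiments with planted truth.

The generator emulates the experimental design the pipeline targets: four
conditions (Control, Hardening, Stress, Combo), two sequencing fractions per
biological sample (total RNA and the polysome-bound fraction), biological
replicates, and two technical repeats per library obtained by binomial
thinning of one latent library.  Regulatory structure is planted on the
log2 scale:

* a transcriptional program tied to hardening — its effects appear in both
  Hardening and Combo, in both fractions (hardening reshapes the
  transcriptome and everything downstream of it);
* a translational program tied to acute stress — its effects appear in
  Stress and Combo, in the polysome fraction only (selective translation
  without transcriptional change);
* a stable core of genes with no effect anywhere;
* co-expression modules driven by per-sample latent factors shared by the
  module's genes — transcriptional modules act on both fractions (and so
  cancel in the polysome/total ratio), translational modules act on the
  polysome fraction only and therefore surface at the translational level.

Counts are negative-binomial (gamma-Poisson) around CPM-style expected
fractions times log-normal library sizes.  The gamma (biological) component
is drawn once per biological sample and shared by its two fractions —
polysome profiling splits one homogenate into the total and polysome
aliquots, so plant-level variability is common to the pair while sequencing
noise is aliquot-level Poisson.  Marginally each library is still
NB(mu, phi).  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .enrichment import AnnotationDB, write_gmt
from .io import CONDITIONS, CountMatrix, validate_sample_sheet, write_counts, write_sample_sheet

PROGRAMS = (
    "transcription_up",
    "transcription_down",
    "translation_up",
    "translation_down",
)


@dataclass
class SimulationConfig:
    n_genes: int = 2000
    conditions: tuple[str, ...] = CONDITIONS
    n_bio_replicates: int = 3
    n_tech_replicates: int = 2
    library_size_mean: float = 5e6
    library_size_log_sd: float = 0.15
    baseline_log2_mean: float = 6.0
    baseline_log2_sd: float = 2.0
    dispersion: float = 0.1
    te_log2_sd: float = 0.5
    n_transcription_up: int = 150
    n_transcription_down: int = 150
    n_translation_up: int = 150
    n_translation_down: int = 150
    n_stable_core: int = 150
    transcription_effect: float = 2.0
    translation_effect: float = 2.0
    n_modules: int = 4
    n_translation_modules: int = 2  # last k of n_modules are polysome-only
    module_size: int = 50
    module_strength: float = 1.0
    n_terms: int = 50
    term_size_range: tuple[int, int] = (10, 100)
    seed: int = 0

    def __post_init__(self) -> None:
        planted = (
            self.n_transcription_up
            + self.n_transcription_down
            + self.n_translation_up
            + self.n_translation_down
            + self.n_stable_core
            + self.n_modules * self.module_size
        )
        if planted > self.n_genes:
            raise ValueError(
                f"planted gene programs ({planted}) exceed n_genes ({self.n_genes})"
            )
        for name in (
            "n_genes", "n_bio_replicates", "n_tech_replicates", "module_size",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.term_size_range[0] <= self.term_size_range[1]):
            raise ValueError("invalid term_size_range")
        if not 0 <= self.n_translation_modules <= self.n_modules:
            raise ValueError("n_translation_modules must be within n_modules")


def _assign_programs(cfg: SimulationConfig) -> pd.DataFrame:
    """Lay out planted programs over gene ids G0000..; blocks are disjoint."""
    genes = [f"G{i:05d}" for i in range(cfg.n_genes)]
    truth = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
    for cond in cfg.conditions:
        truth[f"trans_effect_{cond}"] = 0.0
        truth[f"transl_effect_{cond}"] = 0.0
    truth["program"] = "none"
    truth["stable_core"] = False
    truth["module"] = "none"
    truth["module_level"] = "none"

    cursor = 0

    def take(n: int) -> list[str]:
        nonlocal cursor
        block = genes[cursor : cursor + n]
        cursor += n
        return block

    e_t, e_l = cfg.transcription_effect, cfg.translation_effect
    # hardening-driven transcriptional program (shared by Combo)
    for name, sign, n in (
        ("transcription_up", +1, cfg.n_transcription_up),
        ("transcription_down", -1, cfg.n_transcription_down),
    ):
        block = take(n)
        truth.loc[block, "program"] = name
        for cond in ("Hardening", "Combo"):
            if cond in cfg.conditions:
                truth.loc[block, f"trans_effect_{cond}"] = sign * e_t
    # stress-driven translational program (shared by Combo)
    for name, sign, n in (
        ("translation_up", +1, cfg.n_translation_up),
        ("translation_down", -1, cfg.n_translation_down),
    ):
        block = take(n)
        truth.loc[block, "program"] = name
        for cond in ("Stress", "Combo"):
            if cond in cfg.conditions:
                truth.loc[block, f"transl_effect_{cond}"] = sign * e_l
    core = take(cfg.n_stable_core)
    truth.loc[core, "stable_core"] = True
    n_shared = cfg.n_modules - cfg.n_translation_modules
    for m in range(cfg.n_modules):
        block = take(cfg.module_size)
        truth.loc[block, "module"] = f"M{m + 1}"
        truth.loc[block, "module_level"] = (
            "transcription" if m < n_shared else "translation"
        )
    return truth


def simulate_experiment(
    cfg: SimulationConfig,
) -> tuple[CountMatrix, CountMatrix, pd.DataFrame, pd.DataFrame]:
    """Draw one experiment: (total counts, polysome counts, sample sheet,
    ground truth).  Bit-identical for a fixed config (seed included)."""
    rng = np.random.default_rng(cfg.seed)
    truth = _assign_programs(cfg)
    genes = truth.index

    baseline = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, cfg.n_genes)
    base_te = rng.normal(0.0, cfg.te_log2_sd, cfg.n_genes)

    module_ids = [f"M{m + 1}" for m in range(cfg.n_modules)]
    in_module = {m: (truth["module"] == m).to_numpy() for m in module_ids}
    n_shared = cfg.n_modules - cfg.n_translation_modules
    transcription_modules = module_ids[:n_shared]
    translation_modules = module_ids[n_shared:]

    columns: dict[str, dict[str, np.ndarray]] = {"total": {}, "polysome": {}}
    sheet_rows = []
    for cond in cfg.conditions:
        trans_eff = truth[f"trans_effect_{cond}"].to_numpy()
        transl_eff = truth[f"transl_effect_{cond}"].to_numpy()
        for rep in range(1, cfg.n_bio_replicates + 1):
            factors = rng.normal(0.0, 1.0, cfg.n_modules)  # one biological sample
            # transcriptional modules shift both fractions; translational
            # modules shift the polysome fraction only (selective loading)
            shift_total = np.zeros(cfg.n_genes)
            shift_poly_extra = np.zeros(cfg.n_genes)
            for f_val, m in zip(factors, module_ids):
                if m in transcription_modules:
                    shift_total[in_module[m]] = cfg.module_strength * f_val
                else:
                    shift_poly_extra[in_module[m]] = cfg.module_strength * f_val
            # plant-level biological noise: one homogenate feeds both
            # fractions, so the gamma multiplier is shared between them and
            # each fraction's marginal counts remain NB(mu, phi)
            if cfg.dispersion > 0:
                bio = rng.gamma(
                    shape=1.0 / cfg.dispersion,
                    scale=cfg.dispersion,
                    size=cfg.n_genes,
                )
            else:
                bio = np.ones(cfg.n_genes)
            for fraction in ("total", "polysome"):
                x = baseline + trans_eff + shift_total
                if fraction == "polysome":
                    x = x + base_te + transl_eff + shift_poly_extra
                rel = np.exp2(x)
                rel /= rel.sum()
                libsize = rng.lognormal(
                    np.log(cfg.library_size_mean), cfg.library_size_log_sd
                )
                mu = rel * libsize
                latent = rng.poisson(bio * mu)
                remaining = latent
                for tech in range(1, cfg.n_tech_replicates + 1):
                    if tech < cfg.n_tech_replicates:
                        share = rng.binomial(
                            remaining, 1.0 / (cfg.n_tech_replicates - tech + 1)
                        )
                    else:
                        share = remaining
                    remaining = remaining - share
                    sample_id = f"{cond}_{fraction}_b{rep}_t{tech}"
                    columns[fraction][sample_id] = share
                    sheet_rows.append(
                        {
                            "sample_id": sample_id,
                            "condition": cond,
                            "fraction": fraction,
                            "biological_replicate": rep,
                            "technical_replicate": tech,
                        }
                    )

    total = CountMatrix(
        pd.DataFrame(columns["total"], index=genes, dtype=np.int64), fraction="total"
    )
    poly = CountMatrix(
        pd.DataFrame(columns["polysome"], index=genes, dtype=np.int64),
        fraction="polysome",
    )
    sheet = validate_sample_sheet(pd.DataFrame(sheet_rows))
    return total, poly, sheet, truth


def simulate_annotation(
    truth: pd.DataFrame,
    cfg: SimulationConfig,
    seed: int | None = None,
    program_fraction: float = 0.8,
) -> AnnotationDB:
    """Random gene-set annotation plus one enriched term per planted program.

    Random terms RT### draw members uniformly; each program term PT_<name>
    takes ``program_fraction`` (>= 0.7) of its members from the program and
    the rest from outside it.
    """
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    genes = np.asarray(truth.index)
    lo, hi = cfg.term_size_range
    terms: dict[str, tuple[str, set]] = {}
    for i in range(cfg.n_terms):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(genes, size=min(size, len(genes)), replace=False)
        terms[f"RT{i:03d}"] = (f"random term {i}", set(members))
    for program in PROGRAMS:
        block = truth.index[truth["program"] == program]
        if len(block) == 0:
            continue
        n_in = max(1, int(round(program_fraction * len(block))))
        inside = rng.choice(np.asarray(block), size=n_in, replace=False)
        outside_pool = truth.index[truth["program"] != program]
        n_out = max(0, len(block) - n_in)
        outside = rng.choice(np.asarray(outside_pool), size=n_out, replace=False)
        terms[f"PT_{program}"] = (
            f"planted program term ({program})",
            set(inside) | set(outside),
        )
    return AnnotationDB(terms)


FIXTURE_FILES = {
    "total": "total_counts.tsv",
    "polysome": "polysome_counts.tsv",
    "samples": "samples.tsv",
    "gmt": "annotation.gmt",
    "truth": "ground_truth.tsv",
    "config": "sim_config.yaml",
}


def write_fixture(
    outdir: str | Path, cfg: SimulationConfig | None = None
) -> dict[str, Path]:
    """Simulate and write the full fixture tree (counts, sheet, GMT, truth).

    The default configuration is the experiment emulated throughout: 2000
    genes, 4 conditions x 2 fractions x 3 biological x 2 technical
    replicates = 48 sample columns in total.
    """
    cfg = cfg or SimulationConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    total, poly, sheet, truth = simulate_experiment(cfg)
    db = simulate_annotation(truth, cfg)

    paths = {k: outdir / v for k, v in FIXTURE_FILES.items()}
    write_counts(total, paths["total"])
    write_counts(poly, paths["polysome"])
    write_sample_sheet(sheet, paths["samples"])
    write_gmt(db, paths["gmt"])
    truth.to_csv(paths["truth"], sep="\t", float_format="%.6g")
    with open(paths["config"], "w") as handle:
        yaml.safe_dump(
            {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(cfg).items()},
            handle,
        )
    return paths


def read_ground_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def simulate_two_group(
    n_genes: int = 2000,
    n_per_group: int = 3,
    dispersion: float = 0.1,
    n_spiked: int = 0,
    fold: float = 4.0,
    spiked_mean: float = 80.0,
    baseline_log_mean: float = 4.5,
    baseline_log_sd: float = 1.0,
    seed: int = 0,
) -> tuple[CountMatrix, list[str], list[str], pd.Index]:
    """Two-group NB counts with optional spiked fold-change genes.

    Background gene means are log-normal; the last ``n_spiked`` genes get a
    fixed mean (``spiked_mean``) multiplied by ``fold`` in group B.  Returns
    (counts, group A samples, group B samples, spiked gene ids).
    """
    rng = np.random.default_rng(seed)
    base = np.exp(rng.normal(baseline_log_mean, baseline_log_sd, n_genes))
    if n_spiked:
        base[-n_spiked:] = spiked_mean
    mu_a = np.tile(base[:, None], (1, n_per_group))
    mu_b = mu_a.copy()
    if n_spiked:
        mu_b[-n_spiked:, :] *= fold

    def draw(mu):
        if dispersion > 0:
            lam = rng.gamma(1.0 / dispersion, mu * dispersion)
        else:
            lam = mu
        return rng.poisson(lam)

    y = np.hstack([draw(mu_a), draw(mu_b)])
    genes = pd.Index([f"G{i:05d}" for i in range(n_genes)], name="gene_id")
    samples = [f"A{j}" for j in range(n_per_group)] + [
        f"B{j}" for j in range(n_per_group)
    ]
    cm = CountMatrix(pd.DataFrame(y, index=genes, columns=samples))
    return cm, samples[:n_per_group], samples[n_per_group:], genes[n_genes - n_spiked :]


def simulate_block_expression(
    n_blocks: int = 2,
    block_size: int = 50,
    n_noise_genes: int = 0,
    latent_r: float = 0.8,
    n_samples: int = 16,
    seed: int = 25,
) -> tuple[pd.DataFrame, pd.Series]:
    """Planted-block expression: genes in a block share an orthogonalised
    latent sample factor (between-block latent correlation exactly 0).

    Returns the genes x samples matrix and the true block label per gene
    (noise genes labelled 'none').
    """
    rng = np.random.default_rng(seed)
    F = rng.normal(0.0, 1.0, (n_samples, n_blocks))
    Q, _ = np.linalg.qr(F)
    Q = Q / Q.std(axis=0, ddof=0)
    rows, truth = [], []
    for b in range(n_blocks):
        for _ in range(block_size):
            rows.append(
                np.sqrt(latent_r) * Q[:, b]
                + np.sqrt(1.0 - latent_r) * rng.normal(0.0, 1.0, n_samples)
            )
            truth.append(f"B{b + 1}")
    for _ in range(n_noise_genes):
        rows.append(rng.normal(0.0, 1.0, n_samples))
        truth.append("none")
    genes = pd.Index([f"G{i:05d}" for i in range(len(rows))], name="gene_id")
    X = pd.DataFrame(rows, index=genes, columns=[f"s{j}" for j in range(n_samples)])
    return X, pd.Series(truth, index=genes)


def simulate_hub_expression(
    n_genes: int = 200,
    n_samples: int = 20,
    n_hubs: int = 5,
    seed: int = 17,
) -> pd.DataFrame:
    """Hub-and-spoke latent expression with heterogeneous hub loadings.

    Squared loadings follow an arcsine (Beta(1/2, 1/2)) law, giving a broad,
    right-skewed connectivity distribution — an approximately scale-free
    network after soft thresholding.
    """
    rng = np.random.default_rng(seed)
    hubs = rng.normal(0.0, 1.0, (n_hubs, n_samples))
    rows = []
    for _ in range(n_genes):
        h = hubs[rng.integers(n_hubs)]
        w = np.sqrt(rng.beta(0.5, 0.5))
        rows.append(w * h + np.sqrt(1.0 - w * w) * rng.normal(0.0, 1.0, n_samples))
    return pd.DataFrame(
        rows,
        index=pd.Index([f"G{i:05d}" for i in range(n_genes)], name="gene_id"),
        columns=[f"s{j}" for j in range(n_samples)],
    )
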