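"""Synthetic multi-tissue aging RNA-seq studies with planted ground truth.

The generator emulates the design of a multi-organ mouse aging study:
``n_tissues`` tissues sampled at five ages across the lifespan
(8, 26, 60, 78 and 104 weeks) with ``n_replicates`` animals per
tissue x age. Counts are negative-binomial on a log-normal per-gene
baseline; lncRNAs are drawn at a lower baseline abundance than mRNAs.

Planted structure, with ground-truth labels returned alongside the data:

* **aging-regulated genes** — a log-linear trend in log2(age weeks) on the
  log2-mean scale, reaching ``aging_effect`` log2 units at the oldest vs
  youngest age, up or down, per tissue;
* **tissue-specific genes** — baseline multiplied by ``specificity_boost``
  in one target tissue at every age;
* **co-expression modules** — a shared latent factor per module whose
  stage-wise variance follows a coupling schedule, so that pairwise
  correlations among module genes strengthen with age. Module genes are
  modelled as a late-life-activated program: expressed at a higher
  baseline (``module_baseline_boost``), jointly induced by
  ``module_aging_effect`` log2 units at the oldest age, which both puts
  them into the aging-regulated sets that the network stages operate on
  and reinforces the old-stage correlation the coupling schedule encodes.

The latent factor draw is standardized within each age group (exact zero
mean, unit variance over the replicates of one age). This keeps group
means — and therefore old-vs-young fold changes — untouched by the
coupling term, and makes the realized shared variance per stage
deterministic, so the programmed stage-wise correlation growth is exact
in expectation rather than subject to latent sampling noise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, InputError

#: The five canonical sampling ages (weeks) of the study design.
CANONICAL_AGES: tuple[int, ...] = (8, 26, 60, 78, 104)

#: The 11 organs of the full study design.
FULL_DESIGN_TISSUES: tuple[str, ...] = (
    "brain", "hypothalamus", "lung", "bone_marrow", "gastric_muscle",
    "liver", "kidney", "heart", "iWAT", "eWAT", "BAT",
)


@dataclass(frozen=True)
class ModuleSpec:
    """One planted lncRNA~mRNA co-expression module.

    Parameters
    ----------
    size : total number of genes in the module.
    lnc_frac : fraction of module genes that are lncRNAs.
    coupling : shared-variance fraction per stage (4 values in [0, 1]);
        stage s spans the s-th pair of adjacent ages.
    """

    size: int = 40
    lnc_frac: float = 0.4
    coupling: tuple[float, ...] = (0.1, 0.3, 0.6, 0.9)


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of a synthetic study.

    Defaults reproduce the full 11-tissue x 5-age x 5-replicate design
    (275 samples) at a desk-scale gene count.
    """

    tissue_names: tuple[str, ...] = FULL_DESIGN_TISSUES
    age_points: tuple[int, ...] = CANONICAL_AGES
    n_replicates: int = 5
    n_genes: int = 2000
    frac_lncRNA: float = 0.3
    n_aging_up: int = 60
    n_aging_down: int = 60
    aging_effect: float = 2.0
    n_tissue_specific: int = 250
    specificity_boost: float = 8.0
    #: if set, tissue-specific genes additionally age (upward) with this
    #: log2 effect in their target tissue.
    specific_aging_effect: float | None = None
    module_specs: tuple[ModuleSpec, ...] = (ModuleSpec(),)
    #: tissue in which module coupling acts; defaults to the first tissue.
    module_tissue: str | None = None
    #: log2-scale sd of the module latent factor at coupling 1. The
    #: late-life induction already locks in the old-stage correlation, so
    #: the latent only needs to carry the early/mid-stage coupling.
    module_sigma: float = 1.5
    #: log2 induction of module genes at the oldest age (late-life
    #: activation) so they qualify as aging-regulated despite the latent
    #: variance the coupling adds.
    module_aging_effect: float = 5.0
    #: baseline multiplier for module genes (highly expressed hub program).
    module_baseline_boost: float = 4.0
    nb_dispersion: float = 0.1
    #: natural-log mean/sd of the log-normal mRNA baseline (mean counts).
    baseline_log_mean: float = 6.0
    baseline_log_sd: float = 0.8
    #: multiplicative baseline shift for lncRNAs (drawn ~4x lower).
    lnc_baseline_factor: float = 0.25
    length_range_bp: tuple[int, int] = (500, 10000)
    seed: int = 0

    @property
    def n_tissues(self) -> int:
        return len(self.tissue_names)

    def validate(self) -> None:
        if self.n_tissues < 1 or self.n_genes < 1 or self.n_replicates < 1:
            raise ConfigError("tissues, genes and replicates must be positive")
        if len(set(self.tissue_names)) != self.n_tissues:
            raise ConfigError("duplicate tissue names")
        if len(self.age_points) < 2 or any(
            b <= a for a, b in zip(self.age_points, self.age_points[1:])
        ):
            raise ConfigError("age_points must be strictly increasing")
        if any(a <= 0 for a in self.age_points):
            raise ConfigError("age_points must be positive (weeks)")
        for p, name in ((self.frac_lncRNA, "frac_lncRNA"),):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.n_aging_up < 0 or self.n_aging_down < 0 or self.n_tissue_specific < 0:
            raise ConfigError("planted gene counts must be non-negative")
        if self.specificity_boost <= 0 or self.lnc_baseline_factor <= 0:
            raise ConfigError("multiplicative boosts must be positive")
        if self.nb_dispersion < 0:
            raise ConfigError("nb_dispersion must be >= 0")
        if self.length_range_bp[0] <= 0 or self.length_range_bp[1] < self.length_range_bp[0]:
            raise ConfigError("invalid gene length range")
        for m in self.module_specs:
            if m.size < 2:
                raise ConfigError("module size must be >= 2")
            if not 0.0 <= m.lnc_frac <= 1.0:
                raise ConfigError("module lnc_frac must be in [0, 1]")
            if len(m.coupling) != len(self.age_points) - 1:
                raise ConfigError(
                    "coupling schedule needs one value per stage "
                    f"({len(self.age_points) - 1} stages for {len(self.age_points)} ages)"
                )
            if any(not 0.0 <= c <= 1.0 for c in m.coupling):
                raise ConfigError("coupling values must be in [0, 1]")
        if self.module_specs and self.n_replicates < 3:
            raise ConfigError("module coupling needs >= 3 replicates per age")
        if self.module_tissue is not None and self.module_tissue not in self.tissue_names:
            raise ConfigError(f"module_tissue {self.module_tissue!r} not in tissue_names")
        n_planted = sum(m.size for m in self.module_specs) + self.n_tissue_specific
        if n_planted + self.n_aging_up + self.n_aging_down > self.n_genes:
            raise ConfigError("planted genes exceed n_genes")


def scaled_study_config(n_tissues: int = 3, n_genes: int = 2000, seed: int = 0,
                        **overrides) -> StudyConfig:
    """A desk-scale study: first ``n_tissues`` organs, default plantings."""
    return StudyConfig(
        tissue_names=FULL_DESIGN_TISSUES[:n_tissues], n_genes=n_genes,
        seed=seed, **overrides,
    )


@dataclass
class SyntheticTruth:
    """Planted labels for a synthetic study.

    Attributes
    ----------
    aging : DataFrame (gene_id, tissue, direction, effect) — one row per
        planted aging-regulated (gene, tissue), direction in {up, down}.
    specific : DataFrame (gene_id, tissue) — planted tissue-specific genes.
    modules : DataFrame (gene_id, module_id).
    coupling : module_id -> per-stage coupling schedule.
    module_tissue : tissue in which coupling acts.
    """

    aging: pd.DataFrame
    specific: pd.DataFrame
    modules: pd.DataFrame
    coupling: dict[str, tuple[float, ...]]
    module_tissue: str | None

    def aging_genes(self, tissue: str, direction: str | None = None) -> set[str]:
        t = self.aging[self.aging["tissue"] == tissue]
        if direction is not None:
            t = t[t["direction"] == direction]
        return set(t["gene_id"])

    def module_members(self, module_id: str) -> set[str]:
        return set(self.modules.loc[self.modules["module_id"] == module_id, "gene_id"])

    def to_frame(self) -> pd.DataFrame:
        """Long-format label table (gene_id, tissue, aging_direction,
        specific_tissue, module_id)."""
        rows = []
        for r in self.aging.itertuples(index=False):
            rows.append((r.gene_id, r.tissue, r.direction, "", ""))
        for r in self.specific.itertuples(index=False):
            rows.append((r.gene_id, "", "", r.tissue, ""))
        for r in self.modules.itertuples(index=False):
            rows.append((r.gene_id, "", "", "", r.module_id))
        return pd.DataFrame(
            rows, columns=["gene_id", "tissue", "aging_direction",
                           "specific_tissue", "module_id"],
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame,
                   coupling: dict[str, tuple[float, ...]] | None = None,
                   module_tissue: str | None = None) -> "SyntheticTruth":
        frame = frame.fillna("")
        aging = frame[frame["aging_direction"] != ""][["gene_id", "tissue", "aging_direction"]]
        aging = aging.rename(columns={"aging_direction": "direction"}).copy()
        aging["effect"] = np.nan
        specific = frame[frame["specific_tissue"] != ""][["gene_id", "specific_tissue"]]
        specific = specific.rename(columns={"specific_tissue": "tissue"})
        modules = frame[frame["module_id"] != ""][["gene_id", "module_id"]]
        return cls(aging.reset_index(drop=True), specific.reset_index(drop=True),
                   modules.reset_index(drop=True), coupling or {}, module_tissue)


def stage_coupling_per_age(coupling: tuple[float, ...]) -> np.ndarray:
    """Per-age shared-variance fraction implied by a per-stage schedule.

    Stage s spans ages (s, s+1); an interior age belongs to two stages and
    receives the mean of their couplings, the end ages the end values.
    """
    c = np.asarray(coupling, dtype=float)
    per_age = np.empty(len(c) + 1)
    per_age[0], per_age[-1] = c[0], c[-1]
    per_age[1:-1] = (c[:-1] + c[1:]) / 2.0
    return per_age


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with var = mu + dispersion * mu^2."""
    if dispersion == 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def generate_study(config: StudyConfig):
    """Generate a synthetic study.

    Returns
    -------
    (counts, samples, genes, truth)
        ``counts`` — DataFrame genes x samples of non-negative integers;
        ``samples`` — DataFrame (sample_id, tissue, age_weeks, replicate);
        ``genes`` — DataFrame (gene_id, biotype, length_bp, n_exons,
        n_isoforms); ``truth`` — :class:`SyntheticTruth`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    width = max(5, len(str(n)))
    gene_ids = np.array([f"G{i:0{width}d}" for i in range(1, n + 1)])

    is_lnc = rng.random(n) < config.frac_lncRNA
    biotype = np.where(is_lnc, "lncRNA", "mRNA")
    length_bp = rng.integers(config.length_range_bp[0], config.length_range_bp[1] + 1, n)
    n_exons = np.where(is_lnc, rng.poisson(2.0, n) + 1, rng.poisson(8.0, n) + 1)
    n_isoforms = np.where(is_lnc, rng.poisson(0.6, n) + 1, rng.poisson(2.0, n) + 1)
    genes = pd.DataFrame({
        "gene_id": gene_ids, "biotype": biotype, "length_bp": length_bp,
        "n_exons": n_exons, "n_isoforms": n_isoforms,
    })

    # log2-scale baseline; lncRNAs shifted lower.
    base_ln = rng.normal(config.baseline_log_mean, config.baseline_log_sd, n)
    base_ln = base_ln + np.where(is_lnc, np.log(config.lnc_baseline_factor), 0.0)
    base_log2 = base_ln / np.log(2.0)

    # ---- role assignment (disjoint pools: modules, specific, then aging) --
    idx_all = np.arange(n)
    module_rows, coupling_map = [], {}
    module_idx: list[np.ndarray] = []
    taken = np.zeros(n, dtype=bool)
    lnc_pool = list(rng.permutation(idx_all[is_lnc]))
    mrna_pool = list(rng.permutation(idx_all[~is_lnc]))
    for k, spec in enumerate(config.module_specs, start=1):
        n_lnc = int(round(spec.size * spec.lnc_frac))
        n_lnc = min(n_lnc, len(lnc_pool))
        n_mrna = spec.size - n_lnc
        if n_mrna > len(mrna_pool):
            raise ConfigError("not enough mRNAs for module spec")
        members = np.array([lnc_pool.pop() for _ in range(n_lnc)]
                           + [mrna_pool.pop() for _ in range(n_mrna)])
        taken[members] = True
        mid = f"M{k}"
        module_idx.append(members)
        coupling_map[mid] = tuple(spec.coupling)
        module_rows += [(gene_ids[i], mid) for i in np.sort(members)]
    modules_df = pd.DataFrame(module_rows, columns=["gene_id", "module_id"])

    free = idx_all[~taken]
    spec_idx = rng.choice(free, size=config.n_tissue_specific, replace=False) \
        if config.n_tissue_specific else np.array([], dtype=int)
    taken[spec_idx] = True
    spec_tissue = np.array(config.tissue_names)[
        np.arange(len(spec_idx)) % config.n_tissues]
    spec_tissue = spec_tissue[rng.permutation(len(spec_idx))] if len(spec_idx) else spec_tissue
    specific_df = pd.DataFrame({"gene_id": gene_ids[spec_idx], "tissue": spec_tissue})

    free = idx_all[~taken]
    aging_rows = []
    # effect matrix: signed log2 change at oldest vs youngest, per tissue
    effect = {t: np.zeros(n) for t in config.tissue_names}
    for t in config.tissue_names:
        k = config.n_aging_up + config.n_aging_down
        chosen = rng.choice(free, size=k, replace=False) if k else np.array([], dtype=int)
        up, down = chosen[:config.n_aging_up], chosen[config.n_aging_up:]
        effect[t][up] += config.aging_effect
        effect[t][down] -= config.aging_effect
        aging_rows += [(gene_ids[i], t, "up", config.aging_effect) for i in np.sort(up)]
        aging_rows += [(gene_ids[i], t, "down", config.aging_effect) for i in np.sort(down)]

    # module genes: late-life activation (step at the oldest age), all up
    module_tissue = config.module_tissue or (config.tissue_names[0]
                                             if config.module_specs else None)
    late_effect = np.zeros(n)
    for members in module_idx:
        late_effect[members] += config.module_aging_effect
        base_log2[members] += np.log2(config.module_baseline_boost)
        aging_rows += [
            (gene_ids[i], module_tissue, "up", config.module_aging_effect)
            for i in members
        ]
    if config.specific_aging_effect is not None:
        for i, t in zip(spec_idx, spec_tissue):
            effect[t][i] += config.specific_aging_effect
            aging_rows.append((gene_ids[i], t, "up", config.specific_aging_effect))
    aging_df = pd.DataFrame(aging_rows,
                            columns=["gene_id", "tissue", "direction", "effect"])

    truth = SyntheticTruth(aging_df, specific_df, modules_df, coupling_map,
                           module_tissue)

    # ---- sample table -----------------------------------------------------
    sample_rows = [
        (f"{t}_{a:03d}w_r{r}", t, a, r)
        for t in config.tissue_names
        for a in config.age_points
        for r in range(1, config.n_replicates + 1)
    ]
    samples = pd.DataFrame(sample_rows,
                           columns=["sample_id", "tissue", "age_weeks", "replicate"])

    # ---- counts -----------------------------------------------------------
    ages = np.array(config.age_points, dtype=float)
    age_frac = (np.log2(ages) - np.log2(ages[0])) / (np.log2(ages[-1]) - np.log2(ages[0]))
    spec_boost_log2 = np.log2(config.specificity_boost)

    count_blocks = []
    for t in config.tissue_names:
        n_s = len(ages) * config.n_replicates
        log2mu = np.tile(base_log2[:, None], (1, n_s))
        age_of_col = np.repeat(age_frac, config.n_replicates)
        log2mu += effect[t][:, None] * age_of_col[None, :]
        in_t = spec_idx[spec_tissue == t] if len(spec_idx) else []
        if len(in_t):
            log2mu[in_t, :] += spec_boost_log2
        if t == module_tissue:
            oldest = age_of_col == 1.0
            log2mu[:, oldest] += late_effect[:, None]
            for members, mid in zip(module_idx, coupling_map):
                per_age_c = stage_coupling_per_age(coupling_map[mid])
                loadings = rng.uniform(0.9, 1.1, len(members))
                zeta = rng.normal(size=(len(ages), config.n_replicates))
                zeta = (zeta - zeta.mean(axis=1, keepdims=True)) \
                    / zeta.std(axis=1, keepdims=True)
                z_cols = (np.sqrt(per_age_c)[:, None] * zeta).ravel()
                log2mu[members, :] += (config.module_sigma
                                       * loadings[:, None] * z_cols[None, :])
        mu = np.exp2(log2mu)
        count_blocks.append(_nb_draw(rng, mu, config.nb_dispersion))
    counts = pd.DataFrame(np.hstack(count_blocks), index=pd.Index(gene_ids, name="gene_id"),
                          columns=samples["sample_id"].to_numpy())
    return counts, samples, genes, truth


# ---------------------------------------------------------------------------
# fixtures on disk
# ---------------------------------------------------------------------------

def write_fixtures(counts: pd.DataFrame, samples: pd.DataFrame, genes: pd.DataFrame,
                   truth: SyntheticTruth, directory, config: StudyConfig | None = None,
                   mtx: bool = False) -> dict[str, Path]:
    """Write a study to ``directory`` as plain TSV (+ YAML manifest).

    Returns the mapping of logical names to file paths. With ``mtx=True``
    the counts are additionally written as a MatrixMarket triplet with
    row/column name files.
    """
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # pragma: no cover - OS dependent
        raise InputError(f"cannot create output directory {directory}: {exc}") from exc
    paths = {
        "counts": directory / "counts.tsv",
        "samples": directory / "samples.tsv",
        "genes": directory / "genes.tsv",
        "truth": directory / "truth.tsv",
        "manifest": directory / "manifest.yaml",
    }
    counts.to_csv(paths["counts"], sep="\t", index_label="gene_id")
    samples.to_csv(paths["samples"], sep="\t", index=False)
    genes.to_csv(paths["genes"], sep="\t", index=False)
    truth.to_frame().to_csv(paths["truth"], sep="\t", index=False)
    manifest: dict = {
        "seed": int(config.seed) if config is not None else None,
        "files": {k: v.name for k, v in paths.items() if k != "manifest"},
        "coupling": {k: list(v) for k, v in truth.coupling.items()},
        "module_tissue": truth.module_tissue,
    }
    if config is not None:
        cfg = dataclasses.asdict(config)
        cfg["module_specs"] = [dataclasses.asdict(m) for m in config.module_specs]
        manifest["config"] = cfg
    if mtx:
        from scipy import io as spio
        from scipy import sparse
        paths["counts_mtx"] = directory / "counts.mtx"
        spio.mmwrite(paths["counts_mtx"], sparse.coo_matrix(counts.to_numpy()))
        paths["counts_rows"] = directory / "counts.rows.txt"
        paths["counts_cols"] = directory / "counts.cols.txt"
        paths["counts_rows"].write_text("\n".join(counts.index) + "\n")
        paths["counts_cols"].write_text("\n".join(counts.columns) + "\n")
    with open(paths["manifest"], "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return paths


def read_manifest(directory) -> dict:
    """Read and validate a fixture manifest.

    Raises :class:`InputError` if the manifest's seed disagrees with the
    config stored next to it.
    """
    directory = Path(directory)
    with open(directory / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    cfg = manifest.get("config")
    if cfg is not None and manifest.get("seed") is not None \
            and cfg.get("seed") != manifest["seed"]:
        raise InputError("manifest seed differs from config seed")
    return manifest


def write_synthetic_gmt(genes: pd.DataFrame, truth: SyntheticTruth, path,
                        n_random_terms: int = 30, term_size: tuple[int, int] = (10, 80),
                        seed: int = 0) -> Path:
    """Write a synthetic GMT gene-set collection for enrichment testing.

    Terms comprise random draws from the gene universe plus, per tissue
    with planted aging genes, one "aging-program" term concentrated in the
    planted up-regulated genes of that tissue — giving the enrichment and
    recurrence stages real signal to find. Synthetic stand-in for a curated
    biological-process collection.
    """
    rng = np.random.default_rng(seed)
    universe = genes["gene_id"].to_numpy()
    path = Path(path)
    lines = []
    for k in range(1, n_random_terms + 1):
        size = int(rng.integers(term_size[0], term_size[1] + 1))
        members = rng.choice(universe, size=size, replace=False)
        lines.append("\t".join([f"RND{k:04d}", f"random term {k}", *members]))
    for t in sorted(truth.aging["tissue"].unique()):
        up = sorted(truth.aging_genes(t, "up"))
        if len(up) < 5:
            continue
        core = list(rng.choice(up, size=min(30, len(up)), replace=False))
        pad = list(rng.choice(universe, size=10, replace=False))
        lines.append("\t".join([f"AGING_{t.upper()}", f"aging program {t}",
                                *dict.fromkeys(core + pad)]))
    path.write_text("\n".join(lines) + "\n")
    return path
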