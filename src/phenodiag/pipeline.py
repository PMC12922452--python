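"""Single-call orchestration of the full diagnosis workflow.

``run_pipeline`` executes: read → (outlier removal) → (allometric
correction) → analysis matrix → descriptive stats, non-overlap scan,
univariate suite, PERMDISP + PERMANOVA + validity flag, PCA + PC-wise post
hoc tests, DAPC + jackknife + per-class metrics, and all figures.
Provenance (config snapshot, version, seed, per-stage counts) is written
before any analysis stage; stages are isolated, so one stage's failure is
logged and the rest proceed.  One global seed drives all permutation
stages through derived streams, so identical config + input reproduces
every CSV byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import traceback
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .core_data import MENSURAL, PhenotypeError, PhenotypeMatrix, assign_colors, read_phenotype_csv
from .descriptive import compute_summary_stats
from .diagnosis import NO_NONOVERLAP_MESSAGE, find_nonoverlapping
from .multivariate import (
    assess_validity,
    confusion_matrix,
    classification_metrics,
    dapc_fit,
    euclidean_distances,
    jackknife_classify,
    misclassified_table,
    pc_posthoc,
    pca,
    permanova,
    permdisp,
)
from .preprocess import allometric_correct, remove_outliers
from .univariate import run_univariate
from .viz import ld1_density_plot, ordination_plot, trait_plot

__all__ = ["RunConfig", "RunResult", "run_pipeline"]


@dataclass
class RunConfig:
    """Serializable description of one pipeline run."""

    input: str
    species_column: str = "species"
    drop_columns: list[str] = field(default_factory=list)
    allometric: bool = False
    scaling_trait: str | None = None
    allometry_scope: str = "pooled"          # or "per_taxon"
    outliers: bool = False
    lower_q: float = 0.25
    upper_q: float = 0.75
    iqr_k: float = 1.5
    order: str = "outliers_first"            # or "allometry_first"
    diagnosis_on_raw: bool = False
    hull_taxa: list[str] = field(default_factory=list)
    n_perm: int = 999
    var_threshold: float = 0.90
    alpha: float = 0.05
    dapc_scale: bool = True
    seed: int = 0
    outdir: str = "phenodiag_out"
    skip_stages: list[str] = field(default_factory=list)
    max_figures: int = 60                    # cap on per-trait figure output

    def validate(self) -> None:
        if self.allometric and not self.scaling_trait:
            raise PhenotypeError("allometric=True requires a scaling_trait")
        if self.order not in ("outliers_first", "allometry_first"):
            raise PhenotypeError(f"unknown preprocessing order {self.order!r}")
        if not (0 < self.alpha < 1):
            raise PhenotypeError(f"alpha must be in (0,1), got {self.alpha}")
        if self.n_perm < 1:
            raise PhenotypeError("n_perm must be >= 1")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class RunResult:
    outdir: Path
    tables: dict[str, Path] = field(default_factory=dict)
    figures: dict[str, Path] = field(default_factory=dict)
    errors: dict[str, str] = field(default_factory=dict)
    messages: list[str] = field(default_factory=list)


def _write(df, path: Path, **kw) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, **kw)
    return path


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute every stage of the workflow under ``config.outdir``."""
    config.validate()
    outdir = Path(config.outdir)
    tables_dir, figures_dir, prov_dir = outdir / "tables", outdir / "figures", outdir / "provenance"
    for d in (tables_dir, figures_dir, prov_dir):
        d.mkdir(parents=True, exist_ok=True)
    res = RunResult(outdir=outdir)

    raw = read_phenotype_csv(config.input, config.species_column, config.drop_columns)

    # provenance first: enough to re-execute identically
    config.to_yaml(prov_dir / "config.yaml")
    provenance = {
        "package_version": __version__,
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "seed": config.seed,
        "n_individuals": raw.n_individuals,
        "n_traits": len(raw.trait_names),
        "taxon_levels": raw.taxon_levels,
        "trait_kind": raw.trait_kind,
    }

    # ---- preprocessing ------------------------------------------------
    m = raw
    removal_count = 0

    def do_outliers(mat: PhenotypeMatrix) -> PhenotypeMatrix:
        nonlocal removal_count
        cleaned, log = remove_outliers(mat, config.lower_q, config.upper_q, config.iqr_k)
        removal_count = len(log)
        res.tables["removal_log"] = _write(log.to_frame(), tables_dir / "removal_log.csv", index=False)
        return cleaned

    def do_allometry(mat: PhenotypeMatrix) -> PhenotypeMatrix:
        out = allometric_correct(mat, config.scaling_trait, config.allometry_scope)
        import pandas as pd
        reg = pd.DataFrame(
            [(t, *v) for t, v in out.regressions.items()]
            if config.allometry_scope == "pooled"
            else [(f"{t}[{tax}]", *v) for t, per in out.regressions.items() for tax, v in per.items()],
            columns=["trait", "slope", "intercept", "n"],
        )
        res.tables["allometry_regressions"] = _write(reg, tables_dir / "allometry_regressions.csv", index=False)
        return out.adjusted

    steps = []
    if config.order == "outliers_first":
        if config.outliers:
            steps.append(do_outliers)
        if config.allometric:
            steps.append(do_allometry)
    else:
        if config.allometric:
            steps.append(do_allometry)
        if config.outliers:
            steps.append(do_outliers)
    for step in steps:
        m = step(m)

    provenance["n_removed_outliers"] = removal_count
    provenance["analysis_matrix_shape"] = [m.n_individuals, len(m.trait_names)]
    (prov_dir / "provenance.json").write_text(json.dumps(provenance, indent=2))
    res.tables["analysis_matrix"] = _write(m.to_frame(config.species_column),
                                           tables_dir / "analysis_matrix.csv", index=False)
    colors = assign_colors(m.taxon_levels)

    def stage(name):
        def deco(fn):
            if name in config.skip_stages:
                return
            try:
                fn()
            except Exception as exc:
                res.errors[name] = f"{type(exc).__name__}: {exc}"
                res.messages.append(f"stage {name} failed: {exc}")
                res.messages.append(traceback.format_exc(limit=3))
        return deco

    seeds = np.random.SeedSequence(config.seed).spawn(2)
    seed_disp = int(seeds[0].generate_state(1)[0] % (2**31))
    seed_anova = int(seeds[1].generate_state(1)[0] % (2**31))

    @stage("descriptive")
    def _descriptive():
        summary = compute_summary_stats(m)
        res.tables["summary_stats"] = _write(summary.wide, tables_dir / "summary_stats.csv")
        res.tables["summary_stats_long"] = _write(summary.long, tables_dir / "summary_stats_long.csv", index=False)

    @stage("diagnosis")
    def _diagnosis():
        source = raw if config.diagnosis_on_raw else m
        table = find_nonoverlapping(source)
        res.tables["nonoverlap"] = _write(table, tables_dir / "nonoverlap.csv", index=False)
        if table.empty:
            res.messages.append(NO_NONOVERLAP_MESSAGE)
        for _, row in table.head(config.max_figures).iterrows():
            trait, a, b = row["trait"], row["taxon_a"], row["taxon_b"]
            pair_mask = source.taxa.isin([a, b])
            name = f"nonoverlap_{trait}_{a}_vs_{b}"
            res.figures[name] = trait_plot(
                source.traits.loc[pair_mask, trait], source.taxa[pair_mask],
                source.trait_kind[trait], figures_dir / f"{name}.pdf",
                colors=colors, title=f"{trait}: {a} vs {b}",
            )

    @stage("univariate")
    def _univariate():
        uni = run_univariate(m, alpha=config.alpha)
        res.tables["summary_anova"] = _write(uni.anova_summary, tables_dir / "summary_anova.csv", index=False)
        res.tables["summary_kruskalwallis"] = _write(
            uni.kruskal_summary, tables_dir / "summary_kruskalwallis.csv", index=False)
        for trait, msg in uni.errors.items():
            res.messages.append(f"univariate: trait {trait} failed: {msg}")
        for trait in list(uni.letters)[: config.max_figures]:
            name = f"univariate_{trait}"
            res.figures[name] = trait_plot(
                m.traits[trait], m.taxa, m.trait_kind[trait],
                figures_dir / f"{name}.pdf", letters=uni.letters[trait],
                colors=colors, title=trait,
            )

    @stage("permtests")
    def _permtests():
        import pandas as pd
        dm, groups = euclidean_distances(m)
        disp, disp_pairs = permdisp(dm, groups, n_perm=config.n_perm, seed=seed_disp)
        perm = permanova(dm, groups, n_perm=config.n_perm, seed=seed_anova)
        assess_validity(perm, disp, alpha=config.alpha)
        overall = pd.DataFrame([{"group_a": "(overall)", "group_b": "", "F": disp.F, "p": disp.p}])
        res.tables["permdisp"] = _write(pd.concat([overall, disp_pairs], ignore_index=True),
                                        tables_dir / "permdisp.csv", index=False)
        res.tables["permanova"] = _write(
            pd.DataFrame([{"F": perm.F, "R2": perm.R2, "df_between": perm.df_between,
                           "df_within": perm.df_within, "p": perm.p,
                           "n_perm": perm.n_perm, "valid_flag": perm.valid_flag}]),
            tables_dir / "permanova.csv", index=False)
        if dm.n_dropped:
            res.messages.append(f"permtests: dropped {dm.n_dropped} incomplete rows")

    @stage("pca")
    def _pca():
        import pandas as pd
        cc = m.complete_cases()  # complete-case policy shared by all multivariate stages
        if cc.n_individuals < m.n_individuals:
            res.messages.append(f"pca: dropped {m.n_individuals - cc.n_individuals} incomplete rows")
        ordn = pca(cc)
        scores = ordn.scores.copy()
        scores.insert(0, config.species_column, ordn.groups)
        res.tables["pca_scores"] = _write(scores, tables_dir / "pca_scores.csv")
        res.tables["pca_loadings"] = _write(ordn.loadings, tables_dir / "pca_loadings.csv")
        top = pd.DataFrame({
            ax: ordn.top_contributors(i, 10).index.tolist() + [""] * max(0, 10 - len(ordn.loadings))
            for i, ax in enumerate(ordn.scores.columns[: min(2, ordn.scores.shape[1])])
        })
        res.tables["pca_top_contributors"] = _write(top, tables_dir / "pca_top_contributors.csv", index=False)
        res.tables["pc_posthoc"] = _write(
            pc_posthoc(ordn, cum_threshold=config.var_threshold, alpha=config.alpha),
            tables_dir / "pc_posthoc.csv", index=False)
        if ordn.scores.shape[1] >= 2:
            res.figures["pca"] = ordination_plot(ordn, figures_dir / "pca.pdf",
                                                 hull_taxa=config.hull_taxa, colors=colors,
                                                 title="PCA")
        if ordn.dropped_traits:
            res.messages.append(f"pca: dropped traits {ordn.dropped_traits}")

    @stage("dapc")
    def _dapc():
        ordn, model = dapc_fit(m, var_threshold=config.var_threshold, scale=config.dapc_scale)
        scores = ordn.scores.copy()
        scores.insert(0, config.species_column, ordn.groups)
        res.tables["dapc_scores"] = _write(scores, tables_dir / "dapc_scores.csv")
        if ordn.scores.shape[1] >= 2:
            res.figures["dapc"] = ordination_plot(ordn, figures_dir / "dapc.pdf",
                                                  hull_taxa=config.hull_taxa, colors=colors,
                                                  title="DAPC")
        else:
            res.figures["dapc"] = ld1_density_plot(
                ordn.scores.iloc[:, 0], ordn.groups, figures_dir / "dapc.pdf",
                colors=colors, title="DAPC (LD1)")
        jack = jackknife_classify(m, var_threshold=config.var_threshold, scale=config.dapc_scale)
        res.tables["jackknife"] = _write(jack, tables_dir / "jackknife.csv", index=False)
        done = jack[jack["predicted"].notna()]
        cm = confusion_matrix(done["actual"], done["predicted"])
        res.tables["confusion_matrix"] = _write(cm.counts, tables_dir / "confusion_matrix.csv")
        metrics = classification_metrics(cm)
        per = metrics.per_class.copy()
        per["overall_accuracy"] = metrics.accuracy
        res.tables["class_metrics"] = _write(per, tables_dir / "class_metrics.csv", index=False)
        res.tables["misclassified"] = _write(
            misclassified_table(done["actual"], done["predicted"], done["id"]),
            tables_dir / "misclassified.csv", index=False)

    (outdir / "run.log").write_text("\n".join(res.messages) + "\n" if res.messages else "")
    return res
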