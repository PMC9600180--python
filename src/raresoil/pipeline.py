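"""End-to-end pipeline: simulate or load an OTU table, then run
classification, diversity/LRR, community-structure statistics,
differential abundance, stability-landscape fits and the equilibrium
regressions, writing tidy tab-separated outputs plus a JSON summary.

Every source of randomness is derived from the seeds recorded in the run
configuration, so re-running with an identical configuration reproduces
all outputs bit-identically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .beta import (
    dissimilarity_to_initial,
    neighboring_timepoint_tests,
    pcoa,
    permanova,
    simper,
)
from .classify import Thresholds, category_abundance_flux, classify_taxa, relative_abundance
from .containers import (
    InvalidConfigError,
    OtuTable,
    RECOVERY_TIMEPOINTS,
    SOILS,
    TREATMENTS,
)
from .diffabund import NegativeBinomialDE, responsive_otus
from .diversity import log_response_ratio, lrr_contrasts, rarefy, shannon
from .equilibrium import ratio_dissimilarity_regression, ratio_rare_abundant
from .stability import ORDINAL_TIME, StabilityLandscapeModel
from .synth import CommunityConfig, default_scenarios, generate_initial_community, \
    simulate_disturbance_series

log = logging.getLogger("raresoil")


@dataclass
class RunConfig:
    """Configuration for :func:`run_pipeline`.

    Exactly one of ``counts_path`` (with ``metadata_path``) or
    ``synthetic`` must be provided.
    """

    output_dir: str = "raresoil_out"
    counts_path: str | None = None
    metadata_path: str | None = None
    synthetic: dict | None = None
    rarefy_depth: int | None = None
    rarefy_seed: int = 0
    rare_cutoff: float = 1e-4
    abundant_cutoff: float = 1e-2
    permanova_permutations: int = 999
    permanova_seed: int = 0
    da_shrinkage: float = 10.0
    da_lfc_prior_scale: float = 2.0
    stability: dict = field(default_factory=dict)
    run_da: bool = True
    run_stability: bool = True

    def __post_init__(self) -> None:
        has_files = self.counts_path is not None
        has_synth = self.synthetic is not None
        if has_files == has_synth:
            raise InvalidConfigError(
                "exactly one of counts_path/metadata_path or synthetic must be set"
            )
        if has_files and self.metadata_path is None:
            raise InvalidConfigError("metadata_path required with counts_path")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)


def _load_table(cfg: RunConfig) -> OtuTable:
    if cfg.counts_path is not None:
        if str(cfg.counts_path).endswith(".biom"):
            table = OtuTable.read_biom(cfg.counts_path)
            table.metadata = pd.read_csv(cfg.metadata_path, sep="\t", index_col=0)
            table = OtuTable(table.counts, table.metadata)
        else:
            table = OtuTable.read_tsv(cfg.counts_path, cfg.metadata_path)
        log.info("loaded %d OTUs x %d samples", table.n_otus, len(table.samples))
        return table
    synth_cfg = dict(cfg.synthetic or {})
    community = CommunityConfig(**synth_cfg)
    log.info("simulating community: %s", community)
    initial = generate_initial_community(community)
    return simulate_disturbance_series(initial, default_scenarios(), community)


def _stability_fits(table, div, cfg: RunConfig, outdir: Path) -> pd.DataFrame:
    """Fit the recovery model per (soil, treatment, taxon group).

    The response is each sample's Shannon displacement from the mean
    initial Shannon of the same soil and group, at ordinal model times;
    ambient series are a null control and are not fitted.
    """
    settings = dict(n_walkers=24, n_steps=6_000, n_burn=2_000, thin=4, seed=0)
    settings.update(cfg.stability)
    md = table.metadata
    d = div.merge(md, left_on="sample_id", right_index=True)
    rows = []
    sample_files = []
    for soil in sorted(md["soil"].unique()):
        for g in ("abundant", "rare"):
            block = d[(d["soil"] == soil) & (d["group"] == g)]
            base = block.loc[block["timepoint"] == "initial", "shannon"].mean()
            for tr in sorted(md["treatment"].unique()):
                if tr in ("none", "AMB"):
                    continue
                sub = block[block["treatment"].isin([tr]) | (block["timepoint"] == "initial")]
                sub = sub.dropna(subset=["shannon"])
                t = sub["timepoint"].map(ORDINAL_TIME).to_numpy(dtype=float)
                y = (sub["shannon"] - base).to_numpy(dtype=float)
                if np.unique(t).size < 3:
                    log.warning("skipping %s %s %s: too few timepoints", soil, tr, g)
                    continue
                model = StabilityLandscapeModel(**settings).fit(t, y)
                summ = model.posterior_summary()
                for p in summ.index:
                    rows.append(
                        (soil, tr, g, p, summ.loc[p, "median"],
                         summ.loc[p, "ci_lower"], summ.loc[p, "ci_upper"],
                         model.posterior_skewness(p), float(model.rhat_[p]))
                    )
                fp = outdir / f"posterior_{soil}_{tr}_{g}.tsv"
                model.samples_.to_csv(fp, sep="\t", index=False)
                sample_files.append(fp.name)
                log.info("fitted stability model %s %s %s (converged=%s)",
                         soil, tr, g, model.converged_)
    out = pd.DataFrame(
        rows,
        columns=["soil", "treatment", "group", "parameter", "median",
                 "ci_lower", "ci_upper", "skewness", "rhat"],
    )
    return out


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage and write the report bundle; returns the summary."""
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(outdir / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    log.setLevel(logging.INFO)
    summary: dict = {"version": __version__, "config": asdict(cfg)}
    try:
        stage = "load"
        table = _load_table(cfg)
        table.write_tsv(outdir / "otu_table.tsv", outdir / "metadata.tsv")

        stage = "rarefy"
        if cfg.rarefy_depth is not None:
            table = rarefy(table, cfg.rarefy_depth, cfg.rarefy_seed)
            log.info("rarefied to %d reads (seed %d)", cfg.rarefy_depth, cfg.rarefy_seed)

        stage = "classify"
        rel = relative_abundance(table)
        thresholds = Thresholds(cfg.rare_cutoff, cfg.abundant_cutoff)
        assignments = {}
        for soil in sorted(table.metadata["soil"].unique()):
            sub = rel.subset_samples(table.initial_samples(soil))
            asg = classify_taxa(sub, thresholds)
            soil_rel = rel.subset_samples(
                table.metadata.index[table.metadata["soil"] == soil]
            )
            asg.labels = asg.labels.reindex(soil_rel.proportions.index).fillna("NEW")
            assignments[soil] = asg
            asg.write_tsv(outdir / f"categories_{soil}.tsv")
            summary.setdefault("category_counts", {})[soil] = (
                asg.counts().to_dict()
            )

        stage = "flux"
        flux_shares = []
        for soil, asg in assignments.items():
            soil_rel = rel.subset_samples(
                table.metadata.index[table.metadata["soil"] == soil]
            )
            ts = category_abundance_flux(soil_rel, asg)
            flux_shares.append(ts.shares)
            ts.flows.to_csv(outdir / f"category_flows_{soil}.tsv", sep="\t", index=False)
        pd.concat(flux_shares).to_csv(outdir / "category_shares.tsv", sep="\t", index=False)

        stage = "diversity"
        div_parts = []
        for soil, asg in assignments.items():
            soil_table = table.subset_soil(soil)
            div_parts.append(shannon(soil_table, asg))
        div = pd.concat(div_parts, ignore_index=True)
        div.to_csv(outdir / "shannon.tsv", sep="\t", index=False)
        lrr = log_response_ratio(div, table.metadata)
        lrr.to_csv(outdir / "lrr.tsv", sep="\t", index=False)
        lrr_contrasts(lrr, "group").to_csv(outdir / "lrr_group_tests.tsv", sep="\t", index=False)
        lrr_contrasts(lrr, "soil").to_csv(outdir / "lrr_soil_tests.tsv", sep="\t", index=False)

        stage = "beta"
        perm_rows, simper_rows = [], []
        for soil, asg in assignments.items():
            soil_ids = table.metadata.index[table.metadata["soil"] == soil]
            soil_rel = rel.subset_samples(soil_ids)
            from .beta import bray_curtis  # local to keep module import light

            d = bray_curtis(soil_rel)
            d.write_tsv(outdir / f"bray_curtis_{soil}.tsv")
            ord_res = pcoa(d)
            ord_res.coordinates.to_csv(outdir / f"pcoa_{soil}.tsv", sep="\t")
            md = soil_rel.metadata.copy()
            treated = md.index[md["timepoint"] != "initial"]
            dt = d.to_dataframe().loc[treated, treated]
            from .beta import DistanceMatrix

            perm = permanova(
                DistanceMatrix(dt.to_numpy(), list(treated)),
                md.loc[treated, ["treatment", "timepoint"]],
                n_perm=cfg.permanova_permutations,
                seed=cfg.permanova_seed,
            )
            perm.insert(0, "soil", soil)
            perm_rows.append(perm)

            init = list(md.index[md["timepoint"] == "initial"])
            for tr in sorted(md.loc[treated, "treatment"].unique()):
                for tp in RECOVERY_TIMEPOINTS:
                    cell = list(
                        md.index[(md["treatment"] == tr) & (md["timepoint"] == tp)]
                    )
                    if not cell:
                        continue
                    pair = soil_rel.subset_samples(init + cell)
                    groups = pd.Series(
                        ["initial"] * len(init) + ["treated"] * len(cell),
                        index=init + cell,
                    )
                    sres = simper(pair, groups, asg)
                    simper_rows.append(
                        (soil, tr, tp, sres.mean_dissimilarity,
                         *[sres.taxon_group_percent[g] for g in ("abundant", "common", "rare")])
                    )
            dissim = dissimilarity_to_initial(soil_rel)
            dissim.rename("dissimilarity").to_frame().to_csv(
                outdir / f"dissimilarity_to_initial_{soil}.tsv", sep="\t"
            )
            neighboring_timepoint_tests(dissim, md).to_csv(
                outdir / f"dissimilarity_ttests_{soil}.tsv", sep="\t", index=False
            )
        permr = pd.concat(perm_rows, ignore_index=True)
        permr.to_csv(outdir / "permanova.tsv", sep="\t", index=False)
        simperr = pd.DataFrame(
            simper_rows,
            columns=["soil", "treatment", "timepoint", "mean_bray_curtis",
                     "abundant_pct", "common_pct", "rare_pct"],
        )
        simperr.to_csv(outdir / "simper.tsv", sep="\t", index=False)
        summary["simper_mean_pct"] = {
            "abundant": float(simperr["abundant_pct"].mean()),
            "rare": float(simperr["rare_pct"].mean()),
        }

        stage = "differential_abundance"
        if cfg.run_da:
            da_rows, resp_rows = [], []
            for soil, asg in assignments.items():
                md = table.metadata
                init = table.initial_samples(soil)
                for tr in TREATMENTS:
                    for tp in RECOVERY_TIMEPOINTS:
                        cell = list(
                            md.index[(md["soil"] == soil) & (md["treatment"] == tr)
                                     & (md["timepoint"] == tp)]
                        )
                        if not cell:
                            continue
                        sub = table.subset_samples(init + cell)
                        y = pd.Series(
                            ["initial"] * len(init) + ["treated"] * len(cell),
                            index=init + cell,
                        )
                        de = NegativeBinomialDE(
                            shrinkage=cfg.da_shrinkage,
                            lfc_prior_scale=cfg.da_lfc_prior_scale,
                            ref_level="initial",
                        ).fit(sub, y)
                        res = de.results_
                        res = res.assign(soil=soil, treatment=tr, timepoint=tp)
                        filtered, resp = responsive_otus(res, asg)
                        resp = resp.assign(soil=soil, treatment=tr, timepoint=tp)
                        da_rows.append(res)
                        resp_rows.append(resp)
            pd.concat(da_rows).to_csv(outdir / "da_results.tsv", sep="\t")
            respall = pd.concat(resp_rows, ignore_index=True)
            respall.to_csv(outdir / "responsive_otus.tsv", sep="\t", index=False)
            summary["responsive_counts"] = (
                respall.groupby("treatment")["n_otus"].sum().to_dict()
            )

        stage = "stability"
        if cfg.run_stability:
            fits = _stability_fits(table, div, cfg, outdir)
            fits.to_csv(outdir / "stability_fits.tsv", sep="\t", index=False)
            summary["stability_parameters"] = len(fits)

        stage = "equilibrium"
        reg_rows = []
        for soil, asg in assignments.items():
            soil_ids = table.metadata.index[table.metadata["soil"] == soil]
            soil_rel = rel.subset_samples(soil_ids)
            ratio = ratio_rare_abundant(soil_rel, asg)
            dissim = dissimilarity_to_initial(soil_rel)
            md = soil_rel.metadata
            treated = md.index[md["timepoint"] != "initial"]
            ratio, dissim = ratio.loc[ratio.index.intersection(treated)], dissim
            grouping = md.loc[ratio.index, "treatment"]
            reg = ratio_dissimilarity_regression(ratio, dissim, grouping)
            reg.insert(0, "soil", soil)
            reg_rows.append(reg)
        regs = pd.concat(reg_rows, ignore_index=True)
        regs.to_csv(outdir / "ratio_regressions.tsv", sep="\t", index=False)
        summary["regression_slopes_positive"] = int((regs["slope"] > 0).sum())
        summary["n_regressions"] = int(len(regs))

        with open(outdir / "summary.json", "w") as fhj:
            json.dump(summary, fhj, indent=2, default=str)
        log.info("pipeline complete: %s", outdir)
        return summary
    except Exception as exc:
        log.error("pipeline failed at stage %r: %s", stage, exc)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    finally:
        log.removeHandler(fh)
        fh.close()
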