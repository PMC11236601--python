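"""Configuration-driven orchestration of the full analysis.

Stages (dependency order): simulate (or ingest) → qc → structure →
trial-fit → met-fa → gblup → stability → usefulness. Every stage writes
plain CSV/JSON outputs into the run directory, and a JSON manifest records
the configuration, seeds, per-stage elapsed time, key counts and a SHA-256
checksum of every output file. Unchanged stages are skipped on rerun by
comparing a signature of their parameters and input checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic, genomics, trial_models, met_fa, gblup, stability, usefulness

logger = logging.getLogger("heteropool.pipeline")

STAGES = ["simulate", "qc", "structure", "trial_fit", "met_fa", "gblup",
          "stability", "usefulness"]

STAGE_DEPS = {
    "simulate": [],
    "qc": ["simulate"],
    "structure": ["qc"],
    "trial_fit": ["simulate"],
    "met_fa": ["trial_fit"],
    "gblup": ["qc", "trial_fit"],
    "stability": ["gblup", "met_fa"],
    "usefulness": ["gblup", "structure", "met_fa"],
}


@dataclass
class RunConfig:
    """All pipeline knobs in one place (loadable from YAML)."""

    outdir: str = "heteropool_run"
    seed: int = 1
    preset: str | None = "desk"      # None ⇒ ingest the input paths below
    genotypes_csv: str | None = None
    map_csv: str | None = None
    pheno_csv: str | None = None
    stages: list = field(default_factory=lambda: list(STAGES))
    # simulate (desk preset scale)
    n_sites: int = 8
    n_hybrids: int = 200
    n_parents: int = 40
    n_markers: int = 350
    sigma2_a: float = 0.5
    sigma2_e: float = 1.0
    # qc
    max_het: float = 0.5
    max_missing: float = 0.1
    # structure
    k_min: int = 2
    k_max: int = 6
    cv_folds: int = 3
    # trial models
    genetic_model: str = "additive+sca"
    residual: str = "iid"
    # met fa
    fa_k: int = 2
    n_clusters: int | None = None
    # gblup
    top_fraction: float = 0.10
    # usefulness
    uc_p: float = 0.10
    uc_h: float = 1.0
    n_dh: int = 100
    anchor_group: int | None = None
    max_crosses_per_pair: int | None = 40

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        if self.preset is None:
            for name in ("genotypes_csv", "map_csv", "pheno_csv"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"config requires existing {name} "
                                            "when no preset is used")
        bad = set(self.stages) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _signature(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str)
                          .encode()).hexdigest()


class PipelineRun:
    """Executes enabled stages in dependency order with caching."""

    def __init__(self, config: RunConfig):
        config.validate()
        self.cfg = config
        self.out = Path(config.outdir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.out / "manifest.json"
        self.manifest = {"config": asdict(config), "stages": {}}
        self.prev = {}
        if self.manifest_path.exists():
            try:
                self.prev = json.loads(self.manifest_path.read_text())
            except json.JSONDecodeError:
                self.prev = {}
        handler = logging.FileHandler(self.out / "run.log")
        handler.setFormatter(logging.Formatter(
            "%(asctime)s %(name)s %(levelname)s %(message)s"))
        logging.getLogger("heteropool").addHandler(handler)
        self._log_handler = handler

    # -- helpers ----------------------------------------------------------
    def path(self, name: str) -> Path:
        return self.out / name

    def _stage_signature(self, stage: str, params: dict,
                         inputs: list[str]) -> str:
        in_sums = {}
        for f in inputs:
            p = self.path(f)
            if p.exists():
                in_sums[f] = _sha256(p)
        return _signature({"stage": stage, "params": params,
                           "inputs": in_sums, "seed": self.cfg.seed})

    def _cached(self, stage: str, sig: str, outputs: list[str]) -> bool:
        rec = self.prev.get("stages", {}).get(stage)
        if not rec or rec.get("signature") != sig:
            return False
        for f in outputs:
            p = self.path(f)
            if not p.exists() or _sha256(p) != rec["outputs"].get(f):
                return False
        return True

    def _record(self, stage: str, sig: str, outputs: list[str],
                elapsed: float, counts: dict, cached: bool) -> None:
        self.manifest["stages"][stage] = {
            "signature": sig,
            "outputs": {f: _sha256(self.path(f)) for f in outputs},
            "elapsed_s": round(elapsed, 3),
            "counts": counts,
            "cached": cached,
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        logger.info("stage=%s elapsed=%.2fs cached=%s counts=%s",
                    stage, elapsed, cached, counts)

    def _require(self, stage: str) -> None:
        for dep in STAGE_DEPS[stage]:
            if dep not in self.manifest["stages"]:
                raise RuntimeError(f"stage '{stage}' requires '{dep}' which "
                                   "has not run in this or a previous "
                                   "recorded run")

    # -- stages -----------------------------------------------------------
    def run(self) -> dict:
        enabled = [s for s in STAGES if s in self.cfg.stages]
        # allow downstream stages to rely on previously recorded runs
        for s in STAGES:
            if s not in enabled and s in self.prev.get("stages", {}):
                ok = all(self.path(f).exists()
                         for f in self.prev["stages"][s]["outputs"])
                if ok:
                    self.manifest["stages"][s] = self.prev["stages"][s]
        try:
            for s in enabled:
                self._require(s)
                getattr(self, f"stage_{s}")()
        except Exception:
            logger.exception("pipeline halted in a stage")
            raise
        finally:
            self.manifest_path.write_text(
                json.dumps(self.manifest, indent=2, default=str))
            logging.getLogger("heteropool").removeHandler(self._log_handler)
        return self.manifest

    def stage_simulate(self) -> None:
        cfg = self.cfg
        params = {k: getattr(cfg, k) for k in
                  ("preset", "n_sites", "n_hybrids", "n_parents", "n_markers",
                   "sigma2_a", "sigma2_e", "genotypes_csv", "map_csv",
                   "pheno_csv")}
        outputs = ["genotypes.csv", "map.csv", "pheno.csv", "truth_gca.csv",
                   "truth_membership.csv", "plan.csv"]
        sig = self._stage_signature("simulate", params, [])
        t0 = time.time()
        if self._cached("simulate", sig, outputs):
            self._record("simulate", sig, outputs, time.time() - t0, {}, True)
            return
        if cfg.preset == "desk":
            data = synthetic.desk_preset(seed=cfg.seed, n_sites=cfg.n_sites,
                                         n_hybrids=cfg.n_hybrids,
                                         n_parents=cfg.n_parents,
                                         n_markers=cfg.n_markers,
                                         sigma2_a=cfg.sigma2_a,
                                         sigma2_e=cfg.sigma2_e)
            synthetic.write_dosage_csv(data.panel.genotypes,
                                       self.path("genotypes.csv"))
            synthetic.write_map_csv(data.genetic_map, self.path("map.csv"))
            synthetic.write_pheno_csv(data.pheno, self.path("pheno.csv"))
            data.met_truth.gca.to_csv(self.path("truth_gca.csv"))
            pd.DataFrame({"individual": data.panel.genotypes.individual_ids,
                          "subgroup": data.panel.true_membership}
                         ).to_csv(self.path("truth_membership.csv"), index=False)
            data.plan.crosses.to_csv(self.path("plan.csv"), index=False)
            counts = {"sites": cfg.n_sites, "hybrids": cfg.n_hybrids,
                      "parents": cfg.n_parents, "markers": cfg.n_markers,
                      "plots": len(data.pheno)}
        elif cfg.preset == "full-scale":
            raise NotImplementedError(
                "full-scale preset (24 sites, 722 hybrids, 156 parents, "
                "~7758 SNPs) is defined but not exercised at desk scale; "
                "pass explicit sizes instead")
        else:
            import shutil
            shutil.copy(cfg.genotypes_csv, self.path("genotypes.csv"))
            shutil.copy(cfg.map_csv, self.path("map.csv"))
            shutil.copy(cfg.pheno_csv, self.path("pheno.csv"))
            pheno = synthetic.read_pheno_csv(self.path("pheno.csv"))
            hyb = pheno.loc[~pheno["is_check"],
                            ["entry", "male", "female"]].drop_duplicates()
            hyb.columns = ["hybrid", "male", "female"]
            hyb.to_csv(self.path("plan.csv"), index=False)
            pd.DataFrame().to_csv(self.path("truth_gca.csv"))
            pd.DataFrame().to_csv(self.path("truth_membership.csv"))
            counts = {"plots": len(pheno)}
        self._record("simulate", sig, outputs, time.time() - t0, counts, False)

    def stage_qc(self) -> None:
        cfg = self.cfg
        params = {"max_het": cfg.max_het, "max_missing": cfg.max_missing}
        inputs = ["genotypes.csv"]
        outputs = ["qc_genotypes.csv", "qc_summary.json"]
        sig = self._stage_signature("qc", params, inputs)
        t0 = time.time()
        if self._cached("qc", sig, outputs):
            self._record("qc", sig, outputs, time.time() - t0, {}, True)
            return
        g = synthetic.read_dosage_csv(self.path("genotypes.csv"))
        g1 = genomics.filter_markers(g, cfg.max_het, cfg.max_missing)
        g2 = genomics.prune_complete_ld(g1)
        synthetic.write_dosage_csv(g2, self.path("qc_genotypes.csv"))
        summary = {"input_markers": g.n_markers,
                   "after_het_missing": g1.n_markers,
                   "after_ld_prune": g2.n_markers}
        self.path("qc_summary.json").write_text(json.dumps(summary, indent=2))
        self._record("qc", sig, outputs, time.time() - t0, summary, False)

    def stage_structure(self) -> None:
        cfg = self.cfg
        params = {"k_min": cfg.k_min, "k_max": cfg.k_max, "folds": cfg.cv_folds}
        inputs = ["qc_genotypes.csv"]
        outputs = ["rogers_distance.csv", "pcoa.csv", "admixture_Q.csv",
                   "subgroups.csv", "structure_summary.json"]
        sig = self._stage_signature("structure", params, inputs)
        t0 = time.time()
        if self._cached("structure", sig, outputs):
            self._record("structure", sig, outputs, time.time() - t0, {}, True)
            return
        g = synthetic.read_dosage_csv(self.path("qc_genotypes.csv"))
        d = genomics.rogers_distance(g)
        pd.DataFrame(d.values, index=d.individual_ids,
                     columns=d.individual_ids).to_csv(
            self.path("rogers_distance.csv"))
        pc = genomics.pcoa(d, n_axes=2)
        pd.DataFrame(pc.coordinates, index=pc.individual_ids,
                     columns=[f"PCo{i+1}" for i in
                              range(pc.coordinates.shape[1])]
                     ).to_csv(self.path("pcoa.csv"))
        K_best, curve = genomics.select_K_cv(g, cfg.k_min, cfg.k_max,
                                             folds=cfg.cv_folds, seed=cfg.seed)
        fit = genomics.admixture_fit(g, K=K_best, seed=cfg.seed)
        pd.DataFrame(fit.Q, index=g.individual_ids,
                     columns=[f"Q{k+1}" for k in range(K_best)]
                     ).to_csv(self.path("admixture_Q.csv"))
        sub = genomics.assign_subgroups(fit)
        pd.DataFrame({"individual": g.individual_ids, "subgroup": sub}
                     ).to_csv(self.path("subgroups.csv"), index=False)
        summary = {"selected_K": K_best,
                   "cv_error": {str(k): v for k, v in curve.items()},
                   "loglik": fit.loglik,
                   "pcoa_eigenvalues": pc.eigenvalues[:10].tolist()}
        self.path("structure_summary.json").write_text(
            json.dumps(summary, indent=2))
        self._record("structure", sig, outputs, time.time() - t0,
                     {"selected_K": K_best}, False)

    @staticmethod
    def _incidence_from(crosses: pd.DataFrame) -> pd.DataFrame:
        parents = list(dict.fromkeys(pd.concat([crosses["male"],
                                                crosses["female"]])))
        H = pd.DataFrame(0.0, index=crosses["hybrid"], columns=parents)
        for _, r in crosses.iterrows():
            H.at[r["hybrid"], r["male"]] += 1.0
            H.at[r["hybrid"], r["female"]] += 1.0
        return H

    def stage_trial_fit(self) -> None:
        cfg = self.cfg
        params = {"genetic": cfg.genetic_model, "residual": cfg.residual}
        inputs = ["pheno.csv", "plan.csv"]
        outputs = ["varcomp.csv", "blup_additive.csv", "fit_report.json"]
        sig = self._stage_signature("trial_fit", params, inputs)
        t0 = time.time()
        if self._cached("trial_fit", sig, outputs):
            self._record("trial_fit", sig, outputs, time.time() - t0, {}, True)
            return
        pheno = synthetic.read_pheno_csv(self.path("pheno.csv"))
        H = self._incidence_from(pd.read_csv(
            self.path("plan.csv"), dtype={"hybrid": str, "male": str,
                                          "female": str}))
        spec = trial_models.TrialModelSpec(genetic=cfg.genetic_model,
                                           residual=cfg.residual)
        fits = trial_models.fit_all_sites(pheno, spec, H=H)
        vc_rows, blup_rows, report = [], [], {}
        for site, fit in fits.items():
            for k, v in fit.varcomp.items():
                vc_rows.append((site, k, v, fit.varcomp_se.get(k, np.nan)))
            t = fit.blups["additive"].copy()
            t.insert(0, "site", site)
            blup_rows.append(t)
            report[site] = {"loglik": fit.loglik, "converged": bool(fit.converged),
                            "n_iter": fit.n_iter,
                            "mean_reliability": fit.reliability_summary()}
        pd.DataFrame(vc_rows, columns=["site", "component", "estimate", "se"]
                     ).to_csv(self.path("varcomp.csv"), index=False)
        pd.concat(blup_rows).to_csv(self.path("blup_additive.csv"), index=False)
        self.path("fit_report.json").write_text(json.dumps(report, indent=2))
        self._record("trial_fit", sig, outputs, time.time() - t0,
                     {"sites": len(fits)}, False)

    def stage_met_fa(self) -> None:
        cfg = self.cfg
        params = {"fa_k": cfg.fa_k, "n_clusters": cfg.n_clusters}
        inputs = ["blup_additive.csv"]
        outputs = ["fa_loadings.csv", "genetic_correlation.csv",
                   "env_clusters.csv", "dendrogram.nwk", "met_fa_summary.json"]
        sig = self._stage_signature("met_fa", params, inputs)
        t0 = time.time()
        if self._cached("met_fa", sig, outputs):
            self._record("met_fa", sig, outputs, time.time() - t0, {}, True)
            return
        blups = pd.read_csv(self.path("blup_additive.csv"))
        table = blups[blups["n_obs"] > 0].pivot_table(
            index="level", columns="site", values="blup")
        model = met_fa.fit_fa(table, k=cfg.fa_k)
        pd.DataFrame(model.loadings, index=model.sites,
                     columns=[f"F{j+1}" for j in range(model.k)]
                     ).assign(psi=model.psi).to_csv(self.path("fa_loadings.csv"))
        corr = met_fa.genetic_correlation(model)
        corr.to_csv(self.path("genetic_correlation.csv"))
        clust = met_fa.cluster_sites(corr, n_clusters=cfg.n_clusters)
        pd.DataFrame({"site": clust.sites, "cluster": clust.labels}
                     ).to_csv(self.path("env_clusters.csv"), index=False)
        self.path("dendrogram.nwk").write_text(
            met_fa.dendrogram_newick(clust))
        ve = {m: met_fa.variance_explained(model, m) for m in
              range(1, model.k + 1)}
        summary = {"n_clusters": clust.n_clusters,
                   "variance_explained": {
                       str(m): {"overall_mean": v["overall_mean"],
                                "overall_weighted": v["overall_weighted"]}
                       for m, v in ve.items()},
                   "converged": bool(model.converged)}
        self.path("met_fa_summary.json").write_text(json.dumps(summary, indent=2))
        self._record("met_fa", sig, outputs, time.time() - t0,
                     {"n_clusters": clust.n_clusters}, False)

    def stage_gblup(self) -> None:
        cfg = self.cfg
        params = {"top_fraction": cfg.top_fraction}
        inputs = ["qc_genotypes.csv", "pheno.csv", "plan.csv"]
        outputs = ["grm.csv", "gebv.csv", "marker_effects.csv",
                   "concordance.json"]
        sig = self._stage_signature("gblup", params, inputs)
        t0 = time.time()
        if self._cached("gblup", sig, outputs):
            self._record("gblup", sig, outputs, time.time() - t0, {}, True)
            return
        g = synthetic.read_dosage_csv(self.path("qc_genotypes.csv"))
        grm = gblup.compute_grm(g)
        pd.DataFrame(grm.values, index=grm.ids, columns=grm.ids
                     ).to_csv(self.path("grm.csv"))
        pheno = synthetic.read_pheno_csv(self.path("pheno.csv"))
        H = self._incidence_from(pd.read_csv(
            self.path("plan.csv"), dtype={"hybrid": str, "male": str,
                                          "female": str}))
        rel = trial_models.RelationshipMatrix(values=grm.values, ids=grm.ids,
                                              provenance="genomic")
        spec = trial_models.TrialModelSpec(genetic=cfg.genetic_model,
                                           residual=cfg.residual,
                                           relationship="genomic")
        fits = trial_models.fit_all_sites(pheno, spec, H=H, rel=rel)
        gebv_rows, fx_rows = [], []
        fx_by_site = {}
        gmeta = g
        for site, fit in fits.items():
            gb = fit.blups["additive"].copy()
            gb.insert(0, "site", site)
            gebv_rows.append(gb)
            ghat = gb.set_index("level")["blup"]
            fx = gblup.backsolve_markers(ghat, grm)
            fx_by_site[site] = fx
            prof = gblup.effect_profile(fx, top_fraction=cfg.top_fraction,
                                        chrom=gmeta.chrom, cm=gmeta.cm)
            prof.insert(0, "site", site)
            fx_rows.append(prof)
        pd.concat(gebv_rows).to_csv(self.path("gebv.csv"), index=False)
        pd.concat(fx_rows).to_csv(self.path("marker_effects.csv"), index=False)
        sites = sorted(fx_by_site)
        conc = {}
        for i, a in enumerate(sites):
            for b in sites[i + 1:]:
                conc[f"{a}|{b}"] = gblup.effect_concordance(fx_by_site[a],
                                                            fx_by_site[b])
        self.path("concordance.json").write_text(json.dumps(conc, indent=2))
        self._record("gblup", sig, outputs, time.time() - t0,
                     {"sites": len(fits), "markers": g.n_markers}, False)

    def stage_stability(self) -> None:
        cfg = self.cfg
        params = {}
        inputs = ["gebv.csv", "env_clusters.csv"]
        outputs = ["stability.csv", "quadrant_plot_data.csv"]
        sig = self._stage_signature("stability", params, inputs)
        t0 = time.time()
        if self._cached("stability", sig, outputs):
            self._record("stability", sig, outputs, time.time() - t0, {}, True)
            return
        gebv = pd.read_csv(self.path("gebv.csv"))
        table = gebv[gebv["n_obs"] > 0].pivot_table(index="level",
                                                    columns="site",
                                                    values="blup")
        sub = None
        sub_path = self.path("subgroups.csv")
        if sub_path.exists():
            s = pd.read_csv(sub_path)
            sub = s.set_index("individual")["subgroup"]
        st = stability.stability_table(table, subgroup=sub, complete=False)
        st.to_csv(self.path("stability.csv"), index_label="parent")
        quad = st.reset_index(names="parent")[
            ["parent", "mean_effect", "sqrt_stability", "quadrant"]
            + (["subgroup"] if "subgroup" in st else [])]
        quad.to_csv(self.path("quadrant_plot_data.csv"), index=False)
        self._record("stability", sig, outputs, time.time() - t0,
                     {"parents": len(st)}, False)

    def stage_usefulness(self) -> None:
        cfg = self.cfg
        params = {"p": cfg.uc_p, "h": cfg.uc_h, "n_dh": cfg.n_dh,
                  "anchor": cfg.anchor_group,
                  "max_crosses_per_pair": cfg.max_crosses_per_pair}
        inputs = ["qc_genotypes.csv", "marker_effects.csv", "map.csv",
                  "subgroups.csv"]
        outputs = ["uc.csv", "uc_summary.json"]
        sig = self._stage_signature("usefulness", params, inputs)
        t0 = time.time()
        if self._cached("usefulness", sig, outputs):
            self._record("usefulness", sig, outputs, time.time() - t0, {}, True)
            return
        g = synthetic.read_dosage_csv(self.path("qc_genotypes.csv"))
        gmap = synthetic.read_map_csv(self.path("map.csv"))
        sub = pd.read_csv(self.path("subgroups.csv"))
        labels = sub.set_index("individual")["subgroup"].reindex(
            g.individual_ids).to_numpy(int)
        panel = synthetic.FounderPanel(genotypes=g, true_membership=labels,
                                       subgroup_count=int(labels.max()),
                                       fst=0.0 + 1e-9)
        fx_all = pd.read_csv(self.path("marker_effects.csv"))
        effects_by_site = {
            site: gblup.MarkerEffects(table=t[["marker", "effect"]].copy(),
                                      site=site)
            for site, t in fx_all.groupby("site")}
        pheno = synthetic.read_pheno_csv(self.path("pheno.csv"))
        site_means = pheno.groupby("site")["yield"].mean().to_dict()
        anchor = cfg.anchor_group
        if anchor is None:
            counts = pd.Series(labels).value_counts()
            anchor = int(counts.idxmax())
        uc = usefulness.compare_cross_sets(
            panel, anchor_group=anchor, effects_by_site=effects_by_site,
            gmap=gmap, site_means=site_means, n=cfg.n_dh, p=cfg.uc_p,
            h=cfg.uc_h, seed=cfg.seed,
            max_crosses_per_pair=cfg.max_crosses_per_pair)
        uc.to_csv(self.path("uc.csv"), index=False)
        summ = usefulness.uc_summary(uc)
        self.path("uc_summary.json").write_text(
            summ.to_json(orient="records", indent=2))
        self._record("usefulness", sig, outputs, time.time() - t0,
                     {"crosses": uc[["parent1", "parent2"]]
                      .drop_duplicates().shape[0], "anchor": anchor}, False)


def run_pipeline(config: RunConfig) -> dict:
    """Run all enabled stages; returns the manifest dict."""
    return PipelineRun(config).run()
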