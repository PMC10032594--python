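"""End-to-end orchestration of the analysis stages.

Stages run in dependency order on a synthetic study (or user-supplied
inputs): synth -> tracts -> enrich; synth -> envpca -> assoc (+ mock);
synth -> popgen -> metareg.  Every stage writes its table under the output
directory and the run manifest records versions, seeds, input digests and
per-stage row counts, so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import strhab
from strhab import envspace, io, metareg, popgen, synth, tracts as tracts_mod
from strhab.assoc import best_per_locus, kinship_from_snps, lmm_scan, mock_scan, ols_scan

logger = logging.getLogger(__name__)

STAGES = ("synth", "tracts", "enrich", "envpca", "assoc", "mock", "popgen", "metareg")

_DEFAULTS = {
    "seed": 0,
    "stages": list(STAGES),
    "cohort": {},  # CohortSpec overrides
    "min_units": 4,
    "merge_synonymous": True,
    "retention_rule": "cumulative:0.8",
    "max_axes": 7,
    "enrich_sided": "two",
    "alpha": 0.05,
    "model_alpha": 0.05,
    "mock_seeds": 3,
    "prune": {"size": 10, "step": 1, "threshold": 0.1},
    "snp_prune": {"size": 1000, "step": 20, "threshold": 0.1},
    "prior_sd": 1.0,
    "overlap_draws": 2000,
    "run_lmm": False,
}


@dataclass
class RunConfig:
    """Validated run configuration; unknown keys are rejected."""

    values: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.values) - set(_DEFAULTS)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        merged = {**_DEFAULTS, **self.values}
        bad_stages = set(merged["stages"]) - set(STAGES)
        if bad_stages:
            raise ValueError(f"unknown stages: {sorted(bad_stages)}")
        self.values = merged

    def __getitem__(self, key):
        return self.values[key]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh) or {})


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _require(manifest: dict, stage: str, needed: str) -> None:
    if needed not in manifest["stages"]:
        raise RuntimeError(f"stage '{stage}' requires stage '{needed}' to have run")


def run(config: RunConfig, outdir) -> dict:
    """Execute the configured stages; returns (and writes) the run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = config.values
    manifest: dict = {
        "strhab_version": strhab.__version__,
        "python": platform.python_version(),
        "seed": cfg["seed"],
        "config": {k: v for k, v in cfg.items()},
        "stages": {},
    }

    def record(stage: str, files: dict[str, Path], counts: dict[str, int]) -> None:
        manifest["stages"][stage] = {
            "outputs": {k: str(p.relative_to(outdir)) for k, p in files.items()},
            "digests": {k: _digest(p) for k, p in files.items()},
            "rows": counts,
        }

    state: dict = {}
    try:
        if "synth" in cfg["stages"]:
            spec = synth.CohortSpec(seed=cfg["seed"], **cfg["cohort"])
            bundle = synth.generate_study(spec)
            state["bundle"] = bundle
            files = {
                "cds": outdir / "cds.fasta",
                "genotypes": outdir / "genotypes.tsv",
                "env": outdir / "env.tsv",
                "subpops": outdir / "subpops.tsv",
                "snps": outdir / "snps.tsv",
                "truth": outdir / "truth.json",
            }
            io.write_fasta(bundle.cds, files["cds"])
            bundle.geno.write_tsv(files["genotypes"])
            bundle.env.to_csv(files["env"], sep="\t")
            bundle.subpops.to_frame().to_csv(files["subpops"], sep="\t")
            bundle.snps.to_csv(files["snps"], sep="\t")
            bundle.truth.to_json(files["truth"])
            io.write_track_set(bundle.tracks, outdir / "tracks")
            record("synth", files, {"loci": bundle.geno.n_loci, "accessions": bundle.geno.n_accessions})

        if "tracts" in cfg["stages"]:
            _require(manifest, "tracts", "synth")
            bundle = state["bundle"]
            detected = tracts_mod.detect_coding_strs(
                bundle.cds, min_units=cfg["min_units"], merge_synonymous=cfg["merge_synonymous"]
            )
            state["tracts"] = detected
            features = tracts_mod.intersect_tracts(detected, bundle.tracks)
            state["features"] = features
            f_bed = outdir / "tracts.bed"
            io.write_tracts_bed(detected, f_bed)
            f_feat = outdir / "tract_features.tsv"
            metareg.features_frame(features).to_csv(f_feat, sep="\t", index=False)
            record("tracts", {"bed": f_bed, "features": f_feat}, {"tracts": len(detected)})

        if "enrich" in cfg["stages"]:
            _require(manifest, "enrich", "tracts")
            bundle = state["bundle"]
            universe = {
                (pid, r)
                for pid, length in bundle.tracks.protein_lengths.items()
                for r in range(1, length + 1)
            }
            by_aa: dict[str, set] = {}
            for t in state["tracts"]:
                by_aa.setdefault(t.amino_acid, set()).update(
                    (t.transcript_id, r) for r in t.residues
                )
            regions = {
                name: {(pid, r) for pid, res in track.items() for r in res}
                for name, track in bundle.tracks.named_tracks().items()
            }
            enr = strhab.enrichment_scan(by_aa, regions, universe, sided=cfg["enrich_sided"], alpha=cfg["alpha"])
            f = outdir / "enrichment.tsv"
            enr.to_csv(f, sep="\t", index=False)
            record("enrich", {"table": f}, {"tests": len(enr)})

        if "envpca" in cfg["stages"]:
            _require(manifest, "envpca", "synth")
            bundle = state["bundle"]
            env = envspace.complete_case_filter(bundle.env)
            pca = envspace.decompose(env, rule=cfg["retention_rule"], max_axes=cfg["max_axes"])
            state["pca"] = pca
            files = {
                "scores": outdir / "env_scores.tsv",
                "loadings": outdir / "env_loadings.tsv",
            }
            pca.scores.to_csv(files["scores"], sep="\t")
            pca.loadings.to_csv(files["loadings"], sep="\t")
            record("envpca", files, {"axes": pca.n_axes})

        if "assoc" in cfg["stages"]:
            _require(manifest, "assoc", "envpca")
            bundle = state["bundle"]
            records = ols_scan(bundle.geno, state["pca"], alpha=cfg["alpha"], model_alpha=cfg["model_alpha"])
            if cfg["run_lmm"]:
                K = kinship_from_snps(bundle.snps, **cfg["snp_prune"])
                lmm = lmm_scan(bundle.geno, state["pca"], K)
                records = records.merge(lmm[["locus", "axis", "p_lmm"]], on=["locus", "axis"], how="left")
            state["assoc"] = records
            files = {"records": outdir / "assoc.tsv", "best": outdir / "assoc_best.tsv"}
            records.to_csv(files["records"], sep="\t", index=False)
            best_per_locus(records).to_csv(files["best"], sep="\t", index=False)
            record("assoc", files, {"tests": len(records)})

        if "mock" in cfg["stages"]:
            _require(manifest, "mock", "envpca")
            bundle = state["bundle"]
            fracs = []
            rows = []
            for i in range(cfg["mock_seeds"]):
                res = mock_scan(
                    bundle.geno, state["pca"], seed=cfg["seed"] * 1000 + i,
                    alpha=cfg["alpha"], model_alpha=cfg["model_alpha"],
                )
                fracs.append(res.fraction_significant)
                rows.append(
                    {
                        "mock_seed": cfg["seed"] * 1000 + i,
                        "fraction_significant": res.fraction_significant,
                        "fraction_significant_best": res.fraction_significant_best,
                    }
                )
            f = outdir / "mock.tsv"
            pd.DataFrame(rows).to_csv(f, sep="\t", index=False)
            record("mock", {"table": f}, {"seeds": len(rows)})
            manifest["stages"]["mock"]["mean_fraction_significant"] = float(np.mean(fracs))

        if "popgen" in cfg["stages"]:
            _require(manifest, "popgen", "envpca")
            bundle = state["bundle"]
            freqs = popgen.subpop_allele_frequencies(bundle.geno, bundle.subpops)
            view = popgen.biallelize(freqs)
            pairs, summary = popgen.fst_scan(view)
            state["fst_summary"] = summary
            # prune loci (columns) on their subpop frequency profiles
            pruned = popgen.ld_prune(np.nan_to_num(view.p.T), **cfg["prune"])
            cov = popgen.estimate_covariance(view, loci_idx=pruned)
            sub_env = envspace.subpop_mean_env(bundle.env, bundle.subpops)
            sub_pca = envspace.decompose(sub_env, rule="per_axis_min:0.01")
            bf = popgen.env_bayes_factor(view, sub_pca.scores, cov, prior_sd=cfg["prior_sd"])
            state["bf"] = bf
            files = {
                "fst_pairs": outdir / "fst_pairs.tsv",
                "fst_summary": outdir / "fst_summary.tsv",
                "bf": outdir / "bayes_factors.tsv",
                "covariance": outdir / "covariance.tsv",
            }
            pairs.to_csv(files["fst_pairs"], sep="\t", index=False)
            summary.to_csv(files["fst_summary"], sep="\t", index=False)
            bf.to_csv(files["bf"], sep="\t", index=False)
            cov.to_csv(files["covariance"], sep="\t")
            record("popgen", files, {"loci": len(summary), "bf_tests": len(bf)})
            if "assoc" in state:
                cand_ols = set(state["assoc"].loc[state["assoc"]["bonferroni_significant"], "locus"])
                cand_bf = set(bf.loc[bf["log10_bf"] > 1, "locus"])
                cand_fst = set(summary.loc[summary["outlier"], "locus"])
                universe = set(bundle.geno.loci)
                ov = popgen.overlap_permutation_test(
                    [cand_ols, cand_bf, cand_fst], universe,
                    n_draws=cfg["overlap_draws"], seed=cfg["seed"],
                )
                f_ov = outdir / "overlap.json"
                f_ov.write_text(json.dumps(ov.__dict__, indent=2))
                manifest["stages"]["popgen"]["outputs"]["overlap"] = str(f_ov.relative_to(outdir))
                manifest["stages"]["popgen"]["digests"]["overlap"] = _digest(f_ov)

        if "metareg" in cfg["stages"]:
            _require(manifest, "metareg", "popgen")
            _require(manifest, "metareg", "assoc")
            bundle = state["bundle"]
            features = metareg.features_frame(synth.study_feature_vectors(bundle))
            results = metareg.run_all_meta(
                state["assoc"], state["bf"], state["fst_summary"], features
            )
            rows = []
            for name, res in results.items():
                for term, r in res.coefficients.iterrows():
                    rows.append(
                        {
                            "response": name,
                            "term": term,
                            "estimate": r["estimate"],
                            "t": r["t"],
                            "p": r["p"],
                            "significant": bool(r["significant"]),
                            "alpha_bonferroni": res.alpha_bonferroni,
                        }
                    )
            f = outdir / "metareg.tsv"
            pd.DataFrame(rows).to_csv(f, sep="\t", index=False)
            record("metareg", {"table": f}, {"coefficients": len(rows)})
    except Exception as exc:  # partial manifest on stage failure
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
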