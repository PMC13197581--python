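"""End-to-end orchestration: clones -> diversity -> F_ST -> dispersal ->
network -> regression, from one JSON-serialisable configuration.

Every output file carries provenance (package version, seed, configuration
hash) either as ``#``-comment header lines (CSV) or a ``meta`` block
(JSON). Identical seeds give identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dispersal import DispersalConfig, read_patches_csv, relative_inflow, run_dispersal
from .genotypes import detect_clones, diversity_stats, read_genepop, write_genepop
from .matrices import LabelledMatrix
from .network import DEFAULT_THRESHOLD, betweenness, build_network, node_degree
from .popgen import genets_by_site, pairwise_fst_matrix, wc_fst
from .stats import beta_regression
from .synthetic_data import SynthConfig, simulate_bay, simulate_genotypes, simulate_reproduction

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("clonescape")


@dataclass
class PipelineConfig:
    out_dir: str
    seed: int = 0
    # either a synth block...
    synth: dict | None = None
    # ...or explicit inputs
    genepop_path: str | None = None
    sites_path: str | None = None
    field_path: str | None = None
    patches_path: str | None = None
    # stage parameters
    fst_permutations: int = 499
    network_threshold: float = DEFAULT_THRESHOLD
    dispersal: dict = field(default_factory=dict)
    regression_predictors: tuple = ("log_seed_density", "log_inflow")

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))

    def validate(self) -> None:
        if self.synth is None and self.genepop_path is None:
            raise ValueError("configuration error: need a synth block or a genotype file")
        if self.synth is None:
            for name in ("genepop_path", "sites_path"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise ValueError(f"configuration error: {name} missing or absent")
            wants_inflow = any("inflow" in p for p in self.regression_predictors)
            if wants_inflow and self.field_path is None:
                raise ValueError(
                    "configuration error: regression on inflow requires a current field"
                )

    def canonical_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _meta(config: PipelineConfig) -> dict:
    return {
        "package": f"clonescape {__version__}",
        "seed": config.seed,
        "config_hash": config.canonical_hash(),
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in dependency order; returns the summary dict.

    Writes per-stage CSV/JSON artifacts plus a site summary table and a
    ``summary.json`` of headline statistics into ``config.out_dir``. Any
    stage failure raises with the stage name attached.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = _meta(config)
    summary: dict = {"meta": meta}
    stage = "setup"
    try:
        # ---------------- inputs -------------------------------------
        stage = "synth"
        if config.synth is not None:
            scfg = SynthConfig(**{**config.synth, "seed": config.seed})
            field_, patches = simulate_bay(scfg)
            records = None  # generated after dispersal, from reproduction truth
        else:
            records = read_genepop(config.genepop_path)
            scfg = None
            field_ = patches = None
        # ---------------- dispersal ----------------------------------
        stage = "dispersal"
        inflow = None
        if field_ is not None or config.field_path is not None:
            t0 = time.perf_counter()
            if field_ is None:
                from .dispersal import CurrentField

                field_ = CurrentField.from_netcdf(config.field_path)
                patches = read_patches_csv(config.patches_path)
            dcfg = DispersalConfig(**{"seed": config.seed, **config.dispersal})
            disp = run_dispersal(field_, patches, dcfg)
            disp.probability.to_csv(out / "probability.csv", meta=meta)
            disp.flow.to_csv(out / "flow.csv", meta=meta)
            disp.fate_counts.to_csv(out / "fates.csv")
            inflow = disp.inflow
            inflow.to_csv(out / "inflow.csv")
            log.info("dispersal stage done in %.2fs", time.perf_counter() - t0)
        # ---------------- synthetic reproduction & genotypes ---------
        repro = None
        if config.synth is not None:
            stage = "reproduction"
            # express inflow relative to mean habitat area (the reproduction
            # truth is calibrated for relative inflow of order 0.1-20), and
            # floor zero inflows (sites receiving no settlers in a short
            # desk-scale run) to a tenth of the smallest positive inflow
            rel = inflow / float(np.mean([p.area for p in patches]))
            positive = rel[rel > 0]
            floor = float(positive.min()) / 10 if len(positive) else 1e-6
            inflow = rel.clip(lower=floor)
            repro, rtruth = simulate_reproduction(inflow, scfg)
            repro = repro.set_index("site")
            stage = "synth_genotypes"
            # clonality at each site follows the reproduction truth, so the
            # genotype panel carries the R ~ seed/inflow relationship
            from dataclasses import replace as _replace

            scfg = _replace(
                scfg,
                clonality_targets=tuple(
                    np.clip(repro["R_target"].to_numpy(), 0.05, 1.0)
                ),
            )
            records, truth = simulate_genotypes(scfg)
            write_genepop(records, out / "genotypes.gen")
        # ---------------- clones & diversity -------------------------
        stage = "clones"
        t0 = time.perf_counter()
        parts = detect_clones(records)
        rows = []
        for site, part in parts.items():
            site_samples = [r for r in records if r.site == site]
            div = diversity_stats(site_samples)
            rows.append(
                {
                    "site": site,
                    "N": part.N,
                    "G": part.G,
                    "R": part.R,
                    "largest_clone_fraction": part.largest_clone_fraction,
                    "Na": div.Na,
                    "He": div.He,
                    "Ho": div.Ho,
                }
            )
        site_df = pd.DataFrame(rows).set_index("site")
        log.info("clones stage done in %.2fs", time.perf_counter() - t0)
        # ---------------- F_ST ----------------------------------------
        stage = "fst"
        t0 = time.perf_counter()
        genets = genets_by_site(parts)
        global_fst = wc_fst(genets)
        pw = pairwise_fst_matrix(
            genets, n_perm=config.fst_permutations, seed=config.seed
        )
        pw.theta.to_csv(out / "fst.csv", meta=meta)
        if pw.p_values is not None:
            pw.p_values.to_csv(out / "fst_pvalues.csv", meta=meta)
        summary["global_fst"] = global_fst.theta
        log.info("fst stage done in %.2fs", time.perf_counter() - t0)
        # ---------------- network ------------------------------------
        stage = "network"
        graph = build_network(pw.theta, config.network_threshold)
        deg = node_degree(graph)
        bc = betweenness(graph)
        site_df["degree"] = pd.Series(deg)
        site_df["betweenness"] = pd.Series(bc)
        pd.DataFrame(
            [(u, v, w) for u, v, w in graph.edges], columns=["i", "j", "weight"]
        ).to_csv(out / "edges.csv", index=False)
        # ---------------- reproduction & regression ------------------
        stage = "regression"
        if repro is not None and inflow is not None:
            site_df["seed_density"] = repro["seed_density"]
            site_df["spathe_density"] = repro["spathe_density"]
            site_df["inflow"] = inflow.reindex(site_df.index)
            complete = site_df.dropna(
                subset=["seed_density", "inflow"]
            )
            X = pd.DataFrame(
                {
                    "log_seed_density": np.log(complete["seed_density"]),
                    "log_inflow": np.log(complete["inflow"]),
                }
            )
            fit = beta_regression(
                complete["R"].to_numpy(), X.reset_index(drop=True), squeeze=True
            )
            summary["beta_regression"] = {
                "coef": fit.coef.to_dict(),
                "pseudo_r2": fit.pseudo_r2,
                "phi": fit.phi,
                "aicc": fit.aicc,
                "n": fit.nobs,
            }
            (out / "regression.json").write_text(
                json.dumps({"meta": meta, **summary["beta_regression"]}, indent=2)
            )
        # ---------------- summary ------------------------------------
        stage = "summary"
        with open(out / "sites.csv", "w") as fh:
            for k, v in meta.items():
                fh.write(f"# {k}={v}\n")
            site_df.to_csv(fh)
        summary.update(
            {
                "n_sites": int(len(site_df)),
                "total_samples": int(site_df["N"].sum()),
                "total_mlgs": int(site_df["G"].sum()),
                "mean_R": float(site_df["R"].mean()),
                "mean_Na": float(site_df["Na"].mean()),
                "n_pairwise": pw.n_pairs,
            }
        )
        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return summary
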