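"""End-to-end study pipeline: simulate (or load) -> diversity -> community
comparison -> marker discovery -> dysbiosis ratio -> networks -> gatekeepers.

Every stage writes TSV outputs into the configured directory and registers
them in ``manifest.json`` together with the stage name, parameters and the
stage seed, so a rerun with the same config reproduces byte-identical files.
Stage seeds are spawned deterministically from the master seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import compare, dysbiosis, lefse, network, simulate
from .core import (
    Group, OtuTable, SampleMetadata, Scale, Timepoint, alpha_diversity_table,
    distance_matrix, read_metadata, read_otu_table, read_taxonomy, to_relative,
    write_metadata, write_otu_table,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "cohort_report"]

log = logging.getLogger("dysbionet")

ARMS = {"CCl4": ["C48", "C1W", "C2W"], "MSC": ["M48", "M1W", "M2W"]}
TIMEPOINT_PAIRS = [("M48", "C48"), ("M1W", "C1W"), ("M2W", "C2W")]


class PipelineError(RuntimeError):
    """Stage-tagged pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All pipeline parameters; every CLI flag maps onto one field."""

    out_dir: str = "dysbionet_out"
    seed: int = 0
    # input: synthetic by default, or explicit file paths
    otu_table: str | None = None
    metadata: str | None = None
    taxonomy: str | None = None
    synth_n_otus: int = 150
    synth_depth: int = 30_000
    synth_n_per_cohort: int = 6
    # stage parameters
    permanova_n_perm: int = 999
    pam_k_max: int = 6
    lefse_alpha: float = 0.05
    lda_threshold: float = 2.0
    lefse_n_boot: int = 30
    lidr_transform: str = "log10"
    lidr_pseudocount: float = 0.0
    net_prevalence_min: float = 1 / 3
    net_top_n: int = 1000
    net_n_perm: int = 1000
    net_q_max: float = 0.05
    net_min_support: int = 2
    gatekeeper_n_null: int = 10_000
    gatekeeper_null_model: str = "degree"

    @classmethod
    def smoke(cls, **overrides) -> "PipelineConfig":
        """Reduced-cost profile for smoke runs and tests."""
        defaults = dict(net_n_perm=200, gatekeeper_n_null=1000, permanova_n_perm=499)
        defaults.update(overrides)
        return cls(**defaults)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def validate(self) -> None:
        paths = [p for p in (self.otu_table, self.metadata) if p is not None]
        if (self.otu_table is None) != (self.metadata is None):
            raise ValueError("otu_table and metadata must be given together")
        for p in paths + ([self.taxonomy] if self.taxonomy else []):
            if not Path(p).exists():
                raise ValueError(f"input file not found: {p}")
        if not 0 < self.lefse_alpha < 1 or not 0 < self.net_q_max < 1:
            raise ValueError("alpha and q_max must lie in (0, 1)")
        if self.lidr_transform not in ("log10", "none"):
            raise ValueError("lidr_transform must be log10 or none")


def _stage_seed(master: int, stage: str) -> int:
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


class _Manifest:
    def __init__(self, out: Path, cfg: PipelineConfig):
        self.out = out
        self.entries: list[dict] = []
        self.cfg = cfg

    def add(self, stage: str, path: Path, seed: int | None = None, **params) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.entries.append(
            {"stage": stage, "file": path.name, "sha256": digest, "seed": seed,
             "params": params}
        )
        log.info("stage %s wrote %s (seed=%s)", stage, path.name, seed)

    def write(self, failed_stage: str | None = None) -> Path:
        doc = {"config": asdict(self.cfg), "outputs": self.entries}
        if failed_stage:
            doc["FAILED"] = failed_stage
        path = self.out / "manifest.json"
        path.write_text(json.dumps(doc, indent=2, sort_keys=True))
        return path


def _load_inputs(cfg: PipelineConfig, man: _Manifest):
    out = man.out
    if cfg.otu_table is not None:
        tax = read_taxonomy(cfg.taxonomy) if cfg.taxonomy else None
        table = read_otu_table(cfg.otu_table, taxonomy=tax)
        metadata = read_metadata(cfg.metadata)
        truth = None
    else:
        seed = _stage_seed(cfg.seed, "simulate")
        spec = simulate.default_study_spec(
            seed=seed, n_otus=cfg.synth_n_otus, depth=cfg.synth_depth,
            n_per_cohort=cfg.synth_n_per_cohort,
        )
        table, metadata, truth = simulate.generate_study(spec)
        write_otu_table(table, out / "otu_table.tsv")
        write_metadata(metadata, out / "metadata.tsv")
        (out / "truth.json").write_text(json.dumps(
            {"fold_changes": truth.fold_changes,
             "disease_otus": list(truth.disease_otus),
             "health_otus": list(truth.health_otus),
             "correlated_pairs": [list(p) for p in truth.correlated_pairs]},
            indent=2, sort_keys=True))
        man.add("simulate", out / "otu_table.tsv", seed=seed, depth=cfg.synth_depth)
        man.add("simulate", out / "metadata.tsv", seed=seed)
        man.add("simulate", out / "truth.json", seed=seed)
    by_id = {m.sample_id: m for m in metadata}
    missing = [s for s in table.sample_ids if s not in by_id]
    if missing:
        raise PipelineError("input", f"samples without metadata: {missing[:5]}")
    return table, metadata, by_id


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run every stage; returns the path of the written manifest."""
    try:
        cfg.validate()
    except ValueError as exc:
        raise PipelineError("config", str(exc)) from exc
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    man = _Manifest(out, cfg)
    stage = "input"
    try:
        table, metadata, by_id = _load_inputs(cfg, man)
        cohorts = sorted({m.cohort for m in metadata})
        samples_of = {c: [s for s in table.sample_ids if by_id[s].cohort == c] for c in cohorts}

        stage = "diversity"
        div = alpha_diversity_table(table)
        div["cohort"] = [by_id[s].cohort for s in div.index]
        div.to_csv(out / "diversity.tsv", sep="\t")
        man.add(stage, out / "diversity.tsv")

        stage = "compare"
        seed = _stage_seed(cfg.seed, stage)
        prof = to_relative(table, Scale.UNIT)
        perm_rows, simper_rows = [], []
        for m_c, c_c in TIMEPOINT_PAIRS:
            pair = samples_of.get(m_c, []) + samples_of.get(c_c, [])
            if len(pair) < 4:
                continue
            sub = table.subset_samples(pair)
            labels = [by_id[s].cohort for s in pair]
            d = distance_matrix(to_relative(sub, Scale.UNIT))
            res = compare.permanova(d, labels, n_perm=cfg.permanova_n_perm, seed=seed)
            perm_rows.append({"comparison": f"{m_c} vs {c_c}", "pseudo_F": res.pseudo_F,
                              "r2": res.r2, "p": res.p, "n_perm": res.n_perm})
            sres = compare.simper(to_relative(sub, Scale.UNIT), labels, transform="sqrt")
            for rec in sres.table.head(20).itertuples(index=False):
                simper_rows.append({"comparison": f"{m_c} vs {c_c}",
                                    "overall_dissimilarity": sres.overall_dissimilarity,
                                    **rec._asdict()})
        pd.DataFrame(perm_rows).to_csv(out / "permanova.tsv", sep="\t", index=False)
        pd.DataFrame(simper_rows).to_csv(out / "simper.tsv", sep="\t", index=False)
        man.add(stage, out / "permanova.tsv", seed=seed, n_perm=cfg.permanova_n_perm)
        man.add(stage, out / "simper.tsv", seed=seed)
        treated = [s for s in table.sample_ids if by_id[s].group is not Group.NC]
        d_all = distance_matrix(to_relative(table.subset_samples(treated), Scale.UNIT))
        sel = compare.choose_k(d_all, range(2, min(cfg.pam_k_max, d_all.n - 1) + 1), seed=seed)
        best = sel.results[sel.k_best]
        clusters = pd.DataFrame({
            "sample_id": d_all.ids, "cohort": [by_id[s].cohort for s in d_all.ids],
            "cluster": best.labels, "silhouette": best.silhouettes,
        })
        clusters.attrs["k_best"] = sel.k_best
        clusters.to_csv(out / "clusters.tsv", sep="\t", index=False)
        sel.table.to_csv(out / "silhouette_by_k.tsv", sep="\t", index=False)
        man.add(stage, out / "clusters.tsv", seed=seed, k_best=sel.k_best)
        man.add(stage, out / "silhouette_by_k.tsv", seed=seed)

        stage = "lefse"
        seed = _stage_seed(cfg.seed, stage)
        marker_rows = []
        for arm, arm_cohorts in ARMS.items():
            ids = [s for c in arm_cohorts for s in samples_of.get(c, [])]
            if not ids:
                continue
            sub = table.subset_samples(ids)
            classes = [by_id[s].cohort for s in ids]
            _, tab = lefse.associate_otus(
                sub, classes, alpha=cfg.lefse_alpha, lda_threshold=cfg.lda_threshold,
                n_boot=cfg.lefse_n_boot, seed=seed,
            )
            tab = tab[tab.passed].assign(arm=arm)
            marker_rows.append(tab)
        markers = pd.concat(marker_rows, ignore_index=True) if marker_rows else pd.DataFrame(
            columns=["otu_id", "enriched_class", "kw_p", "lda_score", "passed", "arm"])
        markers.to_csv(out / "markers.tsv", sep="\t", index=False)
        man.add(stage, out / "markers.tsv", seed=seed, alpha=cfg.lefse_alpha,
                lda_threshold=cfg.lda_threshold)

        stage = "lidr"
        seed = _stage_seed(cfg.seed, stage)
        disease, health, screen = dysbiosis.define_marker_sets(
            table, metadata, seed=seed, alpha=cfg.lefse_alpha,
            lda_threshold=cfg.lda_threshold, n_boot=cfg.lefse_n_boot,
        )
        scores = dysbiosis.lidr_table(table, disease, health, pseudocount=cfg.lidr_pseudocount)
        scores["cohort"] = [by_id[s].cohort for s in scores.index]
        scores.to_csv(out / "lidr_per_sample.tsv", sep="\t")
        by_cohort = {c: scores.loc[scores.cohort == c, "lidr"].to_numpy() for c in cohorts}
        dysbiosis.cohort_summary(by_cohort).to_csv(out / "lidr_summary.tsv", sep="\t", index=False)
        test_rows = []
        for arm, arm_cohorts in ARMS.items():
            present = {c: by_cohort[c] for c in arm_cohorts if c in by_cohort}
            if len(present) >= 2:
                t = dysbiosis.compare_lidr(present, transform=cfg.lidr_transform)
                test_rows.append(t.assign(arm=arm))
        if "C48" in by_cohort and "M48" in by_cohort:
            base = compare.t_test(by_cohort["C48"], by_cohort["M48"],
                                  transform=cfg.lidr_transform)
            test_rows.append(pd.DataFrame([{
                "comparison": "C48 vs M48", "method": base.method,
                "statistic": base.statistic, "p": base.p, "p_adjusted": np.nan,
                "arm": "baseline"}]))
        pd.concat(test_rows, ignore_index=True).to_csv(out / "lidr_tests.tsv",
                                                       sep="\t", index=False)
        for name in ("lidr_per_sample.tsv", "lidr_summary.tsv", "lidr_tests.tsv"):
            man.add(stage, out / name, seed=seed,
                    n_disease=len(disease), n_health=len(health))

        stage = "network"
        seed = _stage_seed(cfg.seed, stage)
        nets: dict[str, network.CoNetwork] = {}
        for cohort in cohorts:
            if cohort == "NC":
                continue
            sub = table.subset_samples(samples_of[cohort])
            net = network.build_network(
                sub, prevalence_min=cfg.net_prevalence_min, top_n=cfg.net_top_n,
                n_perm=cfg.net_n_perm, q_max=cfg.net_q_max,
                min_support=cfg.net_min_support, seed=seed,
            )
            nets[cohort] = net
            net.edges.to_csv(out / f"network_{cohort}.tsv", sep="\t", index=False)
            man.add(stage, out / f"network_{cohort}.tsv", seed=seed,
                    n_nodes=len(net.nodes), n_edges=net.n_edges)
            hubs = network.hub_ranking(net)
            hubs.to_csv(out / f"hubs_{cohort}.tsv", sep="\t", index=False)
            man.add(stage, out / f"hubs_{cohort}.tsv", seed=seed)

        stage = "gatekeepers"
        seed = _stage_seed(cfg.seed, stage)
        gk_rows = []
        for cohort, net in nets.items():
            g = net.graph()
            g.remove_nodes_from(list(nx.isolates(g)))
            if g.number_of_edges() < 2 or g.number_of_nodes() < 3:
                continue
            scan = network.gatekeeper_scan(g, n_null=cfg.gatekeeper_n_null,
                                           seed=seed, null_model=cfg.gatekeeper_null_model)
            gk_rows.append(scan.assign(cohort=cohort))
        gk = pd.concat(gk_rows, ignore_index=True) if gk_rows else pd.DataFrame(
            columns=["node", "f_before", "f_after", "delta_f", "p", "significant", "cohort"])
        gk.to_csv(out / "gatekeepers.tsv", sep="\t", index=False)
        man.add(stage, out / "gatekeepers.tsv", seed=seed, n_null=cfg.gatekeeper_n_null)

        stage = "report"
        report = cohort_report(out)
        report.to_csv(out / "cohort_report.tsv", sep="\t", index=False)
        man.add(stage, out / "cohort_report.tsv")
    except PipelineError:
        man.write(failed_stage=stage)
        raise
    except Exception as exc:
        man.write(failed_stage=stage)
        raise PipelineError(stage, str(exc)) from exc
    return man.write()


def cohort_report(out_dir) -> pd.DataFrame:
    """Per-cohort summary assembled from stage outputs; missing stages leave
    explicit gaps (NaN / empty strings) rather than failing."""
    out = Path(out_dir)
    div = pd.read_csv(out / "diversity.tsv", sep="\t") if (out / "diversity.tsv").exists() else None
    if div is None:
        raise PipelineError("report", "diversity output missing")
    rows = []
    lidr_sum = (pd.read_csv(out / "lidr_summary.tsv", sep="\t")
                if (out / "lidr_summary.tsv").exists() else None)
    gk = (pd.read_csv(out / "gatekeepers.tsv", sep="\t")
          if (out / "gatekeepers.tsv").exists() else None)
    for cohort, sub in div.groupby("cohort"):
        row = {
            "cohort": cohort, "n": len(sub),
            "mean_richness": sub.richness.mean(),
            "mean_shannon": sub.shannon.mean(),
            "mean_pielou": sub.pielou.mean(),
            "mean_lidr": np.nan, "se_lidr": np.nan,
            "network_nodes": np.nan, "network_edges": np.nan,
            "gatekeepers": "",
        }
        if lidr_sum is not None and cohort in set(lidr_sum.cohort):
            rec = lidr_sum.set_index("cohort").loc[cohort]
            row["mean_lidr"], row["se_lidr"] = rec["mean_lidr"], rec["se"]
        net_path = out / f"network_{cohort}.tsv"
        if net_path.exists():
            edges = pd.read_csv(net_path, sep="\t")
            row["network_edges"] = len(edges)
            row["network_nodes"] = (len(set(edges.otu_a) | set(edges.otu_b))
                                    if len(edges) else 0)
        if gk is not None and len(gk) and cohort in set(gk.cohort):
            sig = gk[(gk.cohort == cohort) & gk.significant]
            row["gatekeepers"] = ";".join(sorted(sig.node.astype(str)))
        rows.append(row)
    return pd.DataFrame(rows).sort_values("cohort", ignore_index=True)
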