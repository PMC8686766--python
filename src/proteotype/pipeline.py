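"""End-to-end orchestration: configuration, stage sequencing, logging and
the run report.

Stage order mirrors the analysis it reproduces: QC and normalization ->
disease differential abundance (with confounder and storage scans) ->
per-disease k-means endotyping and protein blocks -> set enrichment
(directional NES + EMD ratio, enrichment network, exosome overlap,
cellular-location composition, marker correlation density) -> tissue of
origin and trait association -> clinical statistics.  The run is a pure
function of (inputs, config): identical config and seed reproduce every
output byte for byte.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clinical as clin
from . import data as dio
from . import differential as diff
from . import endotyping as endo
from . import enrichment as enr
from . import origin as org
from . import preprocess as prep
from . import simulate as sim
from .data import DataError

log = logging.getLogger("proteotype")

STAGES = ("simulate", "qc", "differential", "endotype", "enrich", "origin", "clinstats")


@dataclass
class PipelineConfig:
    """Pipeline settings; either ``simulate=True`` (synthetic cohort) or
    the four input paths must be given."""

    out_dir: str = "proteotype_run"
    seed: int | None = None
    simulate: bool = True
    matrix_path: str | None = None
    annotation_path: str | None = None
    clinical_path: str | None = None
    gmt_path: str | None = None
    marker_path: str | None = None
    tissue_path: str | None = None
    alpha: float = 0.05
    enrichment_p: float = 0.001
    overlap_threshold: float = 0.5
    k_per_disease: dict = field(default_factory=lambda: {"COPD": 3, "asthma": 4})
    n_blocks_per_disease: dict = field(default_factory=lambda: {"COPD": 2, "asthma": 6})
    n_perm: int = 1000
    n_restarts: int = 25
    n_random_sets: int = 40
    random_set_size: int = 25

    def validate(self) -> None:
        for name in ("alpha", "enrichment_p", "overlap_threshold"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise DataError(f"{name} must lie in (0, 1), got {v}")
        if self.n_perm > 0 and self.seed is None:
            raise DataError("seed is mandatory when any stage is stochastic")
        if not self.simulate:
            for p in ("matrix_path", "annotation_path", "clinical_path"):
                if getattr(self, p) is None:
                    raise DataError(f"{p} required when simulate is false")

    def to_dict(self) -> dict:
        return asdict(self)


_CONFIG_KEYS = set(PipelineConfig.__dataclass_fields__)


def validate_config(path) -> PipelineConfig:
    """Parse a YAML key-value config file; unknown keys are rejected and
    defaults fill everything not given."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise DataError("config file must be a key-value mapping")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise DataError(f"unknown config key(s): {sorted(unknown)}")
    cfg = PipelineConfig(**raw)
    cfg.validate()
    return cfg


def write_config(cfg: PipelineConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


@dataclass
class RunReport:
    seeds: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)  # stage -> {counts, seconds}
    manifest: list = field(default_factory=list)

    def record(self, stage: str, seconds: float, **counts) -> None:
        self.stages[stage] = {"seconds": round(seconds, 3), **counts}
        log.info("stage %s: %s", stage, counts)

    def add_file(self, path: Path) -> None:
        self.manifest.append(str(path))

    def write(self, path: Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {"seeds": self.seeds, "stages": self.stages, "manifest": self.manifest},
                fh,
                indent=2,
                default=str,
            )


def _write(report: RunReport, out: Path, name: str, df: pd.DataFrame) -> Path:
    path = out / name
    dio.write_table(df, path)
    report.add_file(path)
    return path


def run_pipeline(config: PipelineConfig, until: str = "clinstats") -> RunReport:
    """Execute the pipeline through stage ``until`` (inclusive), writing
    every artifact under ``config.out_dir`` and returning the run report."""
    config.validate()
    if until not in STAGES:
        raise DataError(f"unknown stage {until!r}")
    last = STAGES.index(until)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(seeds={"seed": config.seed})
    rng = np.random.default_rng(config.seed)

    # --- inputs -----------------------------------------------------------
    t0 = time.perf_counter()
    truth = None
    if config.simulate:
        sim_cfg = sim.default_config(seed=config.seed or 0)
        matrix, annotation, clinical, truth = sim.simulate_cohort(sim_cfg)
        sets, markers, atlas = _synthetic_collections(truth, annotation, config, rng)
    else:
        matrix, annotation = dio.read_proteome(config.matrix_path, config.annotation_path)
        clinical = dio.read_clinical(config.clinical_path)
        sets = dio.read_gmt(config.gmt_path) if config.gmt_path else None
        markers = dio.read_marker_list(config.marker_path) if config.marker_path else None
        atlas = dio.read_tissue_matrix(config.tissue_path) if config.tissue_path else None
    report.record(
        "simulate" if config.simulate else "load",
        time.perf_counter() - t0,
        n_probes=len(matrix.probe_ids),
        n_subjects=len(matrix.subject_ids),
    )
    if last == 0:
        dio.write_proteome(matrix, out / "matrix.tsv")
        dio.write_annotation(annotation, out / "annotation.tsv")
        dio.write_clinical(clinical, out / "clinical.tsv")
        for p in ("matrix.tsv", "annotation.tsv", "clinical.tsv"):
            report.add_file(out / p)
        report.write(out / "run_report.json")
        return report

    # --- qc / normalization ----------------------------------------------
    t0 = time.perf_counter()
    matrix, annotation, qc_report = prep.qc_filter(matrix, annotation)
    matrix, scale = prep.median_normalize(matrix)
    log2m = prep.log2_transform(matrix)
    qc_path = out / "qc_report.json"
    with open(qc_path, "w", encoding="utf-8") as fh:
        json.dump(qc_report.to_dict(), fh, indent=2)
    report.add_file(qc_path)
    report.record(
        "qc",
        time.perf_counter() - t0,
        n_retained=qc_report.n_retained,
        n_failed=qc_report.n_failed_qc,
    )
    if last == 1:
        report.write(out / "run_report.json")
        return report

    # --- differential + scans ---------------------------------------------
    t0 = time.perf_counter()
    disease = clinical.subjects["disease"]
    covs = pd.DataFrame(
        {
            "age": clinical.subjects["age"],
            "bmi": clinical.subjects["bmi"],
            "sex_f": (clinical.subjects["sex"] == "F").astype(float),
        }
    )
    de = diff.differential_abundance(log2m, disease)
    de_corrected = diff.differential_abundance(log2m, disease, covariates=covs)
    de_sig = de.significant(config.alpha)
    _write(report, out, "differential.tsv", de.table)
    _write(report, out, "differential_corrected.tsv", de_corrected.table)
    scans = {}
    for cov in ("age", "bmi", "sex"):
        scans[cov] = diff.confounder_scan(log2m, clinical, cov, de_sig, config.alpha)
    storage = prep.storage_time_scan(log2m, clinical, config.alpha)
    scan_df = pd.DataFrame(
        [
            {
                "covariate": c,
                "n_associated": s.n_associated,
                "overlap": s.overlap,
                "expected_overlap": s.expected_overlap,
                "enrichment_p": s.enrichment_p,
            }
            for c, s in scans.items()
        ]
    ).set_index("covariate")
    _write(report, out, "confounder_scan.tsv", scan_df)
    report.record(
        "differential",
        time.perf_counter() - t0,
        n_significant=len(de_sig),
        n_significant_corrected=len(de_corrected.significant(config.alpha)),
        n_common=len(set(de_sig) & set(de_corrected.significant(config.alpha))),
        storage_counts=storage.counts,
        storage_overlap=len(storage.overlap),
    )
    if last == 2:
        report.write(out / "run_report.json")
        return report

    # --- per-disease endotyping --------------------------------------------
    t0 = time.perf_counter()
    endotypes: dict[str, endo.EndotypeResult] = {}
    blocks: dict[str, list[endo.ProteinBlock]] = {}
    for dname in pd.unique(disease):
        sids = [s for s in log2m.subject_ids if disease[s] == dname]
        sub = dio.ProteomeMatrix(log2m.values[sids], log_transformed=True)
        k = config.k_per_disease.get(dname)
        res = endo.kmeans_endotypes(
            sub, k=k, n_restarts=config.n_restarts, seed=config.seed or 0
        )
        sig, contrasts = endo.pairwise_cluster_signature(sub, res.labels, config.alpha)
        res.signature, res.contrasts = sig, contrasts
        endotypes[dname] = res
        if sig:
            blocks[dname] = endo.define_protein_blocks(
                sub, sig, n_blocks=config.n_blocks_per_disease.get(dname), labels=res.labels
            )
        pcs = endo.pca_embed(sub, n_components=2)
        _write(report, out, f"pca_{dname}.tsv", pcs.coordinates)
        _write(
            report,
            out,
            f"endotype_labels_{dname}.tsv",
            res.labels.rename("cluster").to_frame(),
        )
    block_sets = {
        f"{dname}-{b.block_id}": frozenset(
            s for p in b.probes for s in annotation.symbols_for(p)
        )
        for dname, bl in blocks.items()
        for b in bl
    }
    if block_sets:
        gmt = dio.ProteinSetCollection(block_sets, {k: "protein block" for k in block_sets})
        dio.write_gmt(gmt, out / "protein_blocks.gmt")
        report.add_file(out / "protein_blocks.gmt")
    report.record(
        "endotype",
        time.perf_counter() - t0,
        **{
            f"signature_{d}": len(r.signature) for d, r in endotypes.items()
        },
        **{f"k_{d}": r.k for d, r in endotypes.items()},
    )
    if last == 3:
        report.write(out / "run_report.json")
        return report

    # --- enrichment ---------------------------------------------------------
    t0 = time.perf_counter()
    stats_series = pd.Series(de.table["stat"].to_numpy(), index=de.table.index)
    symbol_map = annotation.symbol_map()
    nes = enr.directional_enrichment(
        stats_series, sets, n_perm=config.n_perm, seed=config.seed or 0, symbol_map=symbol_map
    )
    emd = enr.emd_enrichment(
        stats_series, sets, n_perm=config.n_perm, seed=config.seed or 0, symbol_map=symbol_map
    )
    _write(report, out, "enrichment_directional.tsv", nes.table)
    _write(report, out, "enrichment_emd.tsv", emd.table)
    network = enr.enrichment_network(
        emd, sets, p_threshold=config.enrichment_p, overlap_threshold=config.overlap_threshold
    )
    edges = pd.DataFrame(
        [
            {"set_a": a, "set_b": b, "overlap": d["overlap"]}
            for a, b, d in network.graph.edges(data=True)
        ]
    )
    nodes = pd.DataFrame(
        [
            {"set": n, "component": network.components[n], **d}
            for n, d in network.graph.nodes(data=True)
        ]
    )
    if len(nodes):
        nodes = nodes.set_index("set")
    _write(report, out, "network_edges.tsv", edges)
    _write(report, out, "network_nodes.tsv", nodes)

    exo_rows, loc_rows = [], []
    universe = sorted({s for syms in symbol_map.values() for s in syms})
    marker_set = set(markers) & set(universe) if markers else set()
    for name, bl in blocks.items():
        for b in bl:
            bsyms = {s for p in b.probes for s in symbol_map[p]}
            if marker_set:
                ov = enr.hypergeometric_overlap(bsyms, marker_set, universe)
                exo_rows.append(
                    {
                        "block": f"{name}-{b.block_id}",
                        "overlap": ov.overlap,
                        "expected": ov.expected,
                        "log2_fold": ov.log2_fold,
                        "p": ov.p,
                    }
                )
            comp = enr.location_composition(b.probes, annotation, log2m.probe_ids)
            loc_rows.append(
                {
                    "block": f"{name}-{b.block_id}",
                    "chi2": comp.chi2,
                    "p": comp.p,
                    "low_count": comp.low_count,
                }
            )
    if exo_rows:
        _write(report, out, "exosome_overlap.tsv", pd.DataFrame(exo_rows).set_index("block"))
    if loc_rows:
        _write(report, out, "location_composition.tsv", pd.DataFrame(loc_rows).set_index("block"))
    marker_probes = [
        p for p in log2m.probe_ids if set(symbol_map[p]) & marker_set
    ]
    corr_p = None
    if len(marker_probes) >= 2:
        mc = enr.marker_correlation_density(log2m, marker_probes, seed=config.seed or 0)
        corr_p = mc.p
    report.record(
        "enrich",
        time.perf_counter() - t0,
        n_sets=len(sets) if sets else 0,
        n_enriched=len(network.graph.nodes),
        n_networks=network.n_components,
        marker_correlation_p=corr_p,
    )
    if last == 4:
        report.write(out / "run_report.json")
        return report

    # --- origin / trait association -----------------------------------------
    t0 = time.perf_counter()
    slope = clin.annual_change(clinical, "kco")
    trait = slope.per_subject["slope"]
    copd_sids = [s for s in log2m.subject_ids if disease[s] == "COPD"]
    copd_m = dio.ProteomeMatrix(log2m.values[copd_sids], log_transformed=True)
    assoc = org.trait_association(copd_m, trait, name="annual_kco_change")
    _write(report, out, "trait_association.tsv", assoc.table)
    flagged = []
    if atlas is not None and "COPD" in blocks and blocks["COPD"]:
        big = blocks["COPD"][0]
        genes = [s for p in big.probes for s in symbol_map[p] if s in set(atlas.genes)]
        if genes:
            profile = org.tissue_origin_zscores(atlas, sorted(set(genes)))
            _write(report, out, "tissue_origin.tsv", profile.table)
            flagged = profile.flagged(config.alpha)
    comparison_p = {}
    if "COPD" in blocks and len(blocks["COPD"]) >= 2:
        g = blocks["COPD"][0].probes
        h = blocks["COPD"][1].probes
        rest = [p for p in log2m.probe_ids if p not in set(g) | set(h)]
        comp = org.compare_association_distributions(assoc, g, h, rest)
        comparison_p = {f"{a}_vs_{b}": p for (a, b), p in comp.p_values.items()}
    report.record(
        "origin",
        time.perf_counter() - t0,
        n_probes_tested=len(assoc.table),
        tissues_flagged=flagged,
        association_comparison_p=comparison_p,
    )
    if last == 5:
        report.write(out / "run_report.json")
        return report

    # --- clinical statistics -------------------------------------------------
    t0 = time.perf_counter()
    rows = []
    subj = clinical.subjects
    d_levels = list(pd.unique(subj["disease"]))
    if len(d_levels) == 2:
        a = subj.loc[subj["disease"] == d_levels[0]]
        b = subj.loc[subj["disease"] == d_levels[1]]
        for var in ("age", "bmi", "pack_years", "fev1_l", "kco_pct"):
            res = clin.two_sample_t(a[var].dropna().to_numpy(), b[var].dropna().to_numpy())
            rows.append({"comparison": "disease", "variable": var, "test": res.test, "p": res.p})
        tab = [
            [int((a["sex"] == "F").sum()), int((a["sex"] == "M").sum())],
            [int((b["sex"] == "F").sum()), int((b["sex"] == "M").sum())],
        ]
        res = clin.fisher_exact(tab)
        rows.append({"comparison": "disease", "variable": "sex", "test": res.test, "p": res.p})
    km_p = {}
    for dname in d_levels:
        labels = endotypes[dname].labels
        dsub = subj.loc[labels.index]
        for var in ("age", "bmi"):
            res = clin.group_compare(dsub[var].to_numpy(), labels.to_numpy(), "anova")
            rows.append({"comparison": f"{dname} endotypes", "variable": var, "test": res.test, "p": res.p})
        res = clin.group_compare(dsub["blood_eos"].to_numpy(), labels.to_numpy(), "kruskal_wallis")
        rows.append({"comparison": f"{dname} endotypes", "variable": "blood_eos", "test": res.test, "p": res.p})
        surv = clin.km_logrank(
            dsub["exac_time"].to_numpy(), dsub["exac_event"].to_numpy(), labels.to_numpy()
        )
        km_p[dname] = surv.p
        rows.append({"comparison": f"{dname} endotypes", "variable": "exacerbation", "test": "log-rank", "p": surv.p})
        for g, curve in surv.curves.items():
            _write(report, out, f"km_{dname}_cluster{g}.tsv", curve)
        slopes = clin.annual_change(clinical, "kco", groups=labels)
        if slopes.group_stats is not None:
            _write(report, out, f"annual_kco_{dname}.tsv", slopes.group_stats)
    _write(report, out, "clinical_tests.tsv", pd.DataFrame(rows))
    report.record("clinstats", time.perf_counter() - t0, n_tests=len(rows), logrank_p=km_p)
    report.write(out / "run_report.json")
    return report


def _synthetic_collections(truth, annotation, config: PipelineConfig, rng):
    """Protein-set collection, marker list and tissue atlas derived from
    the simulation truth: true blocks plus random sets of matched size."""
    symbol_map = annotation.symbol_map()
    universe = sorted({s for syms in symbol_map.values() for s in syms})
    sets: dict[str, frozenset] = {}
    desc: dict[str, str] = {}
    for name, probes in truth.blocks.items():
        syms = frozenset(s for p in probes for s in symbol_map[p])
        sets[f"true_{name}"] = syms
        desc[f"true_{name}"] = "planted block"
    de_syms = frozenset(s for p in truth.de_probes for s in symbol_map[p])
    sets["true_disease_DE"] = de_syms
    desc["true_disease_DE"] = "planted disease-differential probes"
    for i in range(config.n_random_sets):
        members = rng.choice(universe, size=config.random_set_size, replace=False)
        sets[f"random_{i:02d}"] = frozenset(members)
        desc[f"random_{i:02d}"] = "random set"
    markers = dio.MarkerList([s for p in truth.exo_probes for s in symbol_map[p]][:33])
    g_genes = sorted(
        {s for p in truth.blocks.get("COPD-G", []) for s in symbol_map[p]}
    )
    atlas = sim.simulate_tissue_expression(
        g_genes or universe[:50],
        elevated_tissues=("B lymphoblasts", "CD19+ B cells"),
        background_genes=[s for s in universe if s not in set(g_genes)],
        seed=int(rng.integers(2**31)),
    )
    return dio.ProteinSetCollection(sets, desc), markers, atlas
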