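"""Synthetic-cohort generator with known ground truth.

Generates an aptamer-style RFU matrix plus clinical table emulating a
two-disease airway cohort (COPD and severe asthma) with within-disease
endotype structure.  The generative model on the log2 scale is

    log2 RFU_ps = mu_p
                  + sd * ( delta_p * [s has disease]
                           + shift_pb * [s in endotype b]
                           + sum_c beta_pc * z(covariate_cs)
                           + lambda_p * f_s
                           + gamma_p * storage_s / 1000 )
                  + eps_ps,   eps ~ Normal(0, sd)

where every effect (delta, shift, beta, lambda, gamma) is expressed in
units of the residual SD ``sd`` so two-sample power has a closed form, and
f_s is a per-subject standard-normal latent factor shared by the
exosome-correlated probe block (which makes those probes mutually
correlated above background).  Emitted RFU are 2**log2, optionally times a
per-sample scale factor (removed downstream by median normalization).

Longitudinal visits carry Kco (and FEV1) with per-endotype annual slopes;
time to first exacerbation is exponential with a per-endotype rate,
censored at the follow-up horizon.

Default dimensions and clinical distributions mirror the cohort the
pipeline was designed around: 1233 probes, 34 COPD (endotype sizes
10/19/5) + 51 asthma (21/19/7/4) subjects, 365 disease-differential
probes, asthma signature blocks A-F (230 probes), COPD blocks G (118) and
H (3), and 33 exosome-marker probes drawn from blocks A and H.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import (
    CELLULAR_LOCATIONS,
    ClinicalTable,
    DataError,
    MarkerList,
    ProbeAnnotation,
    ProteomeMatrix,
    TissueExpression,
)

DEFAULT_TISSUES = (
    "B lymphoblasts",
    "CD19+ B cells",
    "CD56+ NK cells",
    "BDCA4+ dendritic cells",
    "CD4+ T cells",
    "CD8+ T cells",
    "CD14+ monocytes",
    "CD33+ myeloid cells",
    "bronchial epithelial cells",
    "whole blood",
    "lung",
    "liver",
    "kidney",
    "heart",
    "skeletal muscle",
) + tuple(f"tissue_{i:02d}" for i in range(16, 80))


@dataclass
class BlockSpec:
    """A co-varying probe block: indices plus a per-endotype shift (in
    residual-SD units) applied to members of each endotype."""

    name: str
    probes: np.ndarray
    shifts: tuple[float, ...]


@dataclass
class DiseaseSpec:
    sizes: tuple[int, ...]  # subjects per endotype
    blocks: list[BlockSpec] = field(default_factory=list)
    kco_slopes: tuple[float, ...] = ()  # per endotype, units/year
    exac_rates: tuple[float, ...] = ()  # per endotype, events/year

    @property
    def n_subjects(self) -> int:
        return sum(self.sizes)


@dataclass
class SimulationConfig:
    n_probes: int = 1233
    diseases: dict[str, DiseaseSpec] = field(default_factory=dict)
    de_probes: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    de_effect: float = 1.0
    covariate_slopes: dict[str, tuple[np.ndarray, float]] = field(default_factory=dict)
    exo_probes: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    exo_loading: float = 1.0
    storage_drift: tuple[np.ndarray, float] | None = None  # (probes, SD per 1000 days)
    noise_sd: float = 0.5
    sample_scale_sd: float = 0.1  # lognormal per-sample scale (pre-normalization)
    baseline_log2: tuple[float, float] = (6.0, 14.0)
    n_multi_symbol: int = 11
    visit_years: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0)
    kco_visit_noise_sd: float = 0.05
    follow_up_years: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise DataError("noise_sd must be positive")
        for arr in self._all_probe_sets():
            arr = np.asarray(arr)
            if len(arr) and (arr.min() < 0 or arr.max() >= self.n_probes):
                raise DataError("probe index set outside probe range")

    def _all_probe_sets(self):
        yield self.de_probes
        yield self.exo_probes
        for spec in self.diseases.values():
            for b in spec.blocks:
                yield b.probes
        for probes, _ in self.covariate_slopes.values():
            yield probes
        if self.storage_drift is not None:
            yield self.storage_drift[0]


@dataclass
class SimulationTruth:
    disease: pd.Series  # subject -> disease
    endotype: pd.Series  # subject -> e.g. "COPD-1"
    de_probes: list[str]
    blocks: dict[str, list[str]]  # "COPD-G" -> probe ids
    exo_probes: list[str]
    config: SimulationConfig

    def block_symbols(self, name: str, annotation: ProbeAnnotation) -> list[str]:
        syms: list[str] = []
        for p in self.blocks[name]:
            syms.extend(annotation.symbols_for(p))
        return sorted(set(syms))


def default_config(seed: int = 0, null: bool = False) -> SimulationConfig:
    """The default simulated world (see module docstring).

    ``null=True`` zeroes every effect (disease, endotype, covariate,
    exosome factor, storage drift) while keeping all dimensions, for
    type-I-error calibration.
    """
    n_probes = 1233
    pos = 0

    def take(n):
        nonlocal pos
        out = np.arange(pos, pos + n)
        pos += n
        return out

    de = take(365)
    # asthma blocks A-F (sum 230), per-endotype shift pattern (4 endotypes)
    a_sizes = {"A": 74, "B": 31, "C": 31, "D": 31, "E": 31, "F": 32}
    a_shift = {
        "A": (0.0, 1.0, 0.0, 1.0),
        "B": (0.0, 1.0, -1.0, 0.0),
        "C": (0.0, 1.0, 0.0, 1.0),
        "D": (0.0, 0.0, 0.0, 1.5),
        "E": (1.0, 1.0, -1.0, 0.0),
        "F": (0.0, 0.0, 1.0, 1.0),
    }
    asthma_blocks = [BlockSpec(k, take(a_sizes[k]), a_shift[k]) for k in a_sizes]
    # COPD: block G decreasing across endotypes, small block H increasing
    copd_blocks = [
        BlockSpec("G", take(118), (1.0, 0.0, -1.0)),
        BlockSpec("H", take(3), (-1.0, 0.0, 1.5)),
    ]
    cov = {
        "age": (take(3), 0.5),
        "bmi": (take(5), 0.5),
        "sex": (take(7), 0.5),
    }
    # 33 exosome-marker probes: 30 from asthma block A, all 3 of COPD block H
    exo = np.concatenate([asthma_blocks[0].probes[:30], copd_blocks[1].probes])
    cfg = SimulationConfig(
        n_probes=n_probes,
        diseases={
            "COPD": DiseaseSpec(
                sizes=(10, 19, 5),
                blocks=copd_blocks,
                kco_slopes=(-0.08, -0.08, -0.005),
                exac_rates=(0.10, 0.05, 0.40),
            ),
            "asthma": DiseaseSpec(
                sizes=(21, 19, 7, 4),
                blocks=asthma_blocks,
                kco_slopes=(-0.02, -0.03, -0.01, -0.04),
                exac_rates=(0.15, 0.35, 0.15, 0.25),
            ),
        },
        de_probes=de,
        de_effect=1.0,
        covariate_slopes=cov,
        exo_probes=exo,
        exo_loading=1.0,
        seed=seed,
    )
    if null:
        cfg = replace(
            cfg,
            de_effect=0.0,
            covariate_slopes={k: (v[0], 0.0) for k, v in cfg.covariate_slopes.items()},
            exo_loading=0.0,
            diseases={
                d: replace(
                    s,
                    blocks=[BlockSpec(b.name, b.probes, tuple(0.0 for _ in b.shifts)) for b in s.blocks],
                    exac_rates=tuple(0.2 for _ in s.exac_rates),
                )
                for d, s in cfg.diseases.items()
            },
        )
    return cfg


def simple_config(
    n_per_group: int,
    n_probes: int = 500,
    n_de: int = 0,
    de_effect: float = 0.0,
    noise_sd: float = 0.5,
    seed: int = 0,
    **kwargs,
) -> SimulationConfig:
    """Two diseases, one endotype each, optional disease-differential
    probes: the minimal world for power and null calibration."""
    return SimulationConfig(
        n_probes=n_probes,
        diseases={
            "COPD": DiseaseSpec(sizes=(n_per_group,), kco_slopes=(-0.05,), exac_rates=(0.2,)),
            "asthma": DiseaseSpec(sizes=(n_per_group,), kco_slopes=(-0.02,), exac_rates=(0.2,)),
        },
        de_probes=np.arange(n_de),
        de_effect=de_effect,
        noise_sd=noise_sd,
        seed=seed,
        **kwargs,
    )


# clinical sampling parameters per disease: (mean, sd) or probability
_CLIN = {
    "COPD": dict(
        age=(67.2, 7.1), female_p=0.06, bmi=(22.9, 3.4), pack=(64.9, 27.1),
        blood_eos_med=218.0, fev1_l=(1.74, 0.50), fev1_pct=(62.9, 16.2),
        kco_pct=(66.1, 20.7), dlco_pct=(78.0, 21.1), ics=(200.0, 300.0),
        ocs_p=0.0, storage=(4123.0, 4804.0), sputum_eos_med=2.0,
    ),
    "asthma": dict(
        age=(61.2, 11.6), female_p=0.43, bmi=(25.1, 5.7), pack=(26.5, 27.2),
        blood_eos_med=405.0, fev1_l=(2.22, 0.71), fev1_pct=(86.0, 15.2),
        kco_pct=(104.8, 25.6), dlco_pct=(102.1, 20.1), ics=(1550.0, 400.0),
        ocs_p=0.45, storage=(1429.0, 2316.0), sputum_eos_med=15.0,
    ),
}


def _simulate_clinical(config: SimulationConfig, rng) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    rows = []
    disease_labels, endo_labels = {}, {}
    for disease, spec in config.diseases.items():
        params = _CLIN.get(disease, _CLIN["COPD"])
        for endo_idx, size in enumerate(spec.sizes, start=1):
            for _ in range(size):
                sid = f"S{len(rows)+1:03d}"
                disease_labels[sid] = disease
                endo_labels[sid] = f"{disease}-{endo_idx}"
                rows.append(
                    {
                        "subject_id": sid,
                        "disease": disease,
                        "age": rng.normal(*params["age"]),
                        "sex": "F" if rng.random() < params["female_p"] else "M",
                        "bmi": max(15.0, rng.normal(*params["bmi"])),
                        "pack_years": max(0.0, rng.normal(*params["pack"])),
                        "blood_eos": params["blood_eos_med"] * rng.lognormal(0.0, 0.9),
                        "sputum_eos": min(80.0, params["sputum_eos_med"] * rng.lognormal(0.0, 1.0)),
                        "fev1_l": max(0.4, rng.normal(*params["fev1_l"])),
                        "fev1_pct": max(20.0, rng.normal(*params["fev1_pct"])),
                        "kco_pct": max(20.0, rng.normal(*params["kco_pct"])),
                        "dlco_pct": max(20.0, rng.normal(*params["dlco_pct"])),
                        "ics_dose": max(0.0, rng.normal(*params["ics"])),
                        "ocs_use": bool(rng.random() < params["ocs_p"]),
                        "storage_days": rng.uniform(*params["storage"]),
                    }
                )
    subjects = pd.DataFrame(rows).set_index("subject_id")
    return subjects, pd.Series(disease_labels, name="disease"), pd.Series(endo_labels, name="endotype")


def _simulate_annotation(config: SimulationConfig, probe_ids, rng) -> ProbeAnnotation:
    n = config.n_probes
    # location frequencies approximating an aptamer panel (secreted-rich)
    loc = rng.choice(CELLULAR_LOCATIONS, size=n, p=(0.17, 0.17, 0.20, 0.36, 0.10))
    symbols, uniprot = [], []
    multi = set(rng.choice(n, size=min(config.n_multi_symbol, n), replace=False))
    for i in range(n):
        if i in multi:
            symbols.append((f"GENE{i:04d}", f"GENE{i:04d}B"))
            uniprot.append((f"U{i:05d}", f"U{i:05d}B"))
        else:
            symbols.append((f"GENE{i:04d}",))
            uniprot.append((f"U{i:05d}",))
    table = pd.DataFrame(
        {
            "protein_symbols": symbols,
            "uniprot": uniprot,
            "cellular_location": loc,
            "qc_pass": True,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    return ProbeAnnotation(table)


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[ProteomeMatrix, ProbeAnnotation, ClinicalTable, SimulationTruth]:
    """Generate (RFU matrix, probe annotation, clinical table, truth) from
    the generative model; identical config and seed give identical output."""
    rng = np.random.default_rng(config.seed)
    probe_ids = [f"P{i:04d}" for i in range(config.n_probes)]
    subjects, disease, endotype = _simulate_clinical(config, rng)
    annotation = _simulate_annotation(config, probe_ids, rng)
    n_p, n_s = config.n_probes, len(subjects)
    sd = config.noise_sd

    mu = rng.uniform(*config.baseline_log2, size=n_p)
    log2 = np.tile(mu[:, None], (1, n_s))

    diseases = list(config.diseases)
    if len(diseases) >= 2 and len(config.de_probes):
        # second disease carries the shift; sign random per probe
        signs = rng.choice((-1.0, 1.0), size=len(config.de_probes))
        in_b = (disease == diseases[1]).to_numpy()
        log2[np.ix_(config.de_probes, np.arange(n_s))] += (
            sd * config.de_effect * signs[:, None] * in_b[None, :]
        )

    endo_arr = endotype.to_numpy()
    for dname, spec in config.diseases.items():
        for block in spec.blocks:
            for endo_idx, shift in enumerate(block.shifts, start=1):
                if shift == 0.0:
                    continue
                mask = endo_arr == f"{dname}-{endo_idx}"
                log2[np.ix_(block.probes, np.where(mask)[0])] += sd * shift

    for cov_name, (probes, slope) in config.covariate_slopes.items():
        if slope == 0.0 or not len(probes):
            continue
        if cov_name == "sex":
            z = (subjects["sex"] == "F").to_numpy(dtype=float)
            z = (z - z.mean()) / (z.std() if z.std() > 0 else 1.0)
        else:
            v = subjects[cov_name].to_numpy(dtype=float)
            z = (v - v.mean()) / (v.std() if v.std() > 0 else 1.0)
        log2[np.ix_(probes, np.arange(n_s))] += sd * slope * z[None, :]

    latent = rng.standard_normal(n_s)
    if len(config.exo_probes) and config.exo_loading != 0.0:
        log2[np.ix_(config.exo_probes, np.arange(n_s))] += (
            sd * config.exo_loading * latent[None, :]
        )

    if config.storage_drift is not None:
        probes, gamma = config.storage_drift
        storage = subjects["storage_days"].to_numpy(dtype=float)
        if gamma != 0.0 and len(probes):
            log2[np.ix_(probes, np.arange(n_s))] += sd * gamma * (storage / 1000.0)[None, :]

    log2 += rng.normal(0.0, sd, size=(n_p, n_s))
    rfu = 2.0**log2
    if config.sample_scale_sd > 0:
        rfu *= rng.lognormal(0.0, config.sample_scale_sd, size=n_s)[None, :]
    matrix = ProteomeMatrix(
        pd.DataFrame(rfu, index=probe_ids, columns=subjects.index)
    )

    blocks = {
        f"{d}-{b.name}": [probe_ids[i] for i in b.probes]
        for d, spec in config.diseases.items()
        for b in spec.blocks
    }
    truth = SimulationTruth(
        disease=disease,
        endotype=endotype,
        de_probes=[probe_ids[i] for i in config.de_probes],
        blocks=blocks,
        exo_probes=[probe_ids[i] for i in config.exo_probes],
        config=config,
    )
    clinical = ClinicalTable(subjects)
    clinical = simulate_longitudinal(truth, config, clinical, seed=int(rng.integers(2**31)))
    return matrix, annotation, clinical, truth


def simulate_longitudinal(
    truth: SimulationTruth,
    config: SimulationConfig,
    clinical: ClinicalTable,
    seed: int = 0,
) -> ClinicalTable:
    """Fill visit and exacerbation fields: per-subject Kco trajectories
    kco = baseline + endotype slope * t + noise, and exponential time to
    first exacerbation with the endotype's rate, censored at follow-up."""
    rng = np.random.default_rng(seed)
    subjects = clinical.subjects.copy()
    visit_rows = []
    exac_time = np.empty(len(subjects))
    exac_event = np.empty(len(subjects), dtype=bool)
    for i, sid in enumerate(subjects.index):
        endo = truth.endotype[sid]
        dname, idx = endo.rsplit("-", 1)
        spec = config.diseases[dname]
        e = int(idx) - 1
        slope = spec.kco_slopes[e] if spec.kco_slopes else 0.0
        rate = spec.exac_rates[e] if spec.exac_rates else 0.0
        if rate < 0:
            raise DataError("exacerbation rate must be non-negative")
        kco0 = max(0.3, rng.normal(1.2, 0.3))
        fev0 = subjects.loc[sid, "fev1_l"]
        for t in config.visit_years:
            visit_rows.append(
                {
                    "subject_id": sid,
                    "time_years": float(t),
                    "kco": kco0 + slope * t + rng.normal(0.0, config.kco_visit_noise_sd),
                    "fev1": fev0 - 0.03 * t + rng.normal(0.0, 0.05),
                }
            )
        t_event = rng.exponential(1.0 / rate) if rate > 0 else np.inf
        exac_event[i] = t_event <= config.follow_up_years
        exac_time[i] = min(t_event, config.follow_up_years)
    subjects["exac_time"] = exac_time
    subjects["exac_event"] = exac_event
    return ClinicalTable(subjects, pd.DataFrame(visit_rows))


def simulate_tissue_expression(
    group_genes,
    elevated_tissues,
    tissues=DEFAULT_TISSUES,
    n_background: int = 400,
    shift_sd: float = 2.0,
    seed: int = 0,
    background_genes=None,
) -> TissueExpression:
    """Gene x tissue atlas in which the group genes' expression is shifted
    upward by ``shift_sd`` within-tissue SD units in ``elevated_tissues``
    only; background genes are exchangeable across tissues."""
    tissues = list(tissues)
    unknown = set(elevated_tissues) - set(tissues)
    if unknown:
        raise DataError(f"unknown tissue name(s): {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    group = list(group_genes)
    if background_genes is None:
        background = [f"BG{i:04d}" for i in range(n_background)]
    else:
        background = list(background_genes)
    genes = group + background
    base = rng.normal(7.0, 1.0, size=len(tissues))  # per-tissue baseline
    X = base[None, :] + rng.standard_normal((len(genes), len(tissues)))
    for t in elevated_tissues:
        X[: len(group), tissues.index(t)] += shift_sd
    return TissueExpression(
        pd.DataFrame(X, index=pd.Index(genes, name="gene"), columns=tissues)
    )
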