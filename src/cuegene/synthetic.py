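"""Synthetic study generator with known ground truth.

Emulates the processed layer of a factorial culture experiment — four
isolates x two media (rich/poor nitrogen) x nine replicates — consisting
of sample metadata, per-sample phenotype measurements, an annotated gene
x sample count matrix, and a ground-truth ledger.

The generative direction is marker expression -> flux: per-sample ln
expression of the growth marker (1,3-beta-glucan synthase, EC 2.4.1.34)
and the respiration marker (2-oxoglutarate dehydrogenase, EC 1.2.4.2) is
drawn from additive isolate + medium (+ interaction + replicate) effects,
and the true fluxes follow the planted power laws

    mu   = e^alpha1 * GT48^beta1 * e^eps1,   eps1 ~ N(0, sigma1)
    qCO2 = e^alpha2 * KGD^beta2  * e^eps2,   eps2 ~ N(0, sigma2)

so that a log-log regression of rate on marker expression is the
correctly specified model and recovery of (alpha, beta) is well-posed.
Phenotype measurements are produced by inverting the flux equations
(exponential growth and the closed-loop ideal-gas CO2 conversion), and
expression is converted to integer counts through inverse-RPKM at drawn
library sizes with Poisson noise (a noise-free rounding mode exists; in
that mode the planted power laws are re-anchored on the realized count
table so the round trip is exact).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .expression import CountMatrix, GeneAnnotation, aggregate_by_ec, rpkm_normalize
from .physiology import PhenotypeRecord, PhysioConstants, biomass_carbon, co2_to_respiration

__all__ = [
    "MARKER_ECS",
    "StudyConfig",
    "SyntheticTruth",
    "SyntheticStudy",
    "generate_study",
    "generate_counts",
    "invert_physiology",
    "tiny_fixture",
]

#: EC numbers of the a-priori marker candidates.
MARKER_ECS = {
    "gt48": "2.4.1.34",  # 1,3-beta-glucan synthase (growth marker)
    "gt2": "2.4.1.16",  # chitin synthase (alternative growth candidate)
    "kgd": "1.2.4.2",  # 2-oxoglutarate dehydrogenase (respiration marker)
    "idh_nad": "1.1.1.41",  # NAD-dependent isocitrate dehydrogenase
    "idh_nadp": "1.1.1.42",  # NADP-dependent isocitrate dehydrogenase
    "gs": "6.3.1.2",  # glutamine synthetase (N-limitation indicator)
}


@dataclass(frozen=True)
class StudyConfig:
    """Study design, planted relationships and noise levels.

    Defaults describe a 4-isolate x 2-media x 9-replicate culture study
    whose marker-flux coefficients and residual spreads match the scales
    reported for real fungal cultures (growth model intercept -9.64,
    slope 1.4, residual SE 0.45; respiration model -6.37, 0.98, 0.47).
    Ten samples are dropped as sequencing failures so that 62 usable
    samples remain, the size of the real deposited design.

    Marker expression is in ln(RPKM).  Isolate effects are fixed offsets
    (one per isolate); the medium effect is the rich-minus-poor contrast;
    interaction offsets are drawn N(0, interaction_sd) per cell and
    replicate noise N(0, replicate_sd) per sample.
    """

    n_isolates: int = 4
    n_media: int = 2
    n_replicates: int = 9
    n_genes: int = 2000
    n_ec_classes: int = 450
    library_size_mean: float = 5e6
    library_size_dispersion: float = 0.2  # ln-scale SD

    # planted flux models
    alpha1: float = -9.64
    beta1: float = 1.4
    sigma1: float = 0.45
    alpha2: float = -6.37
    beta2: float = 0.98
    sigma2: float = 0.47

    # marker expression structure (ln RPKM)
    gt48_base: float = 5.5
    kgd_base: float = 6.0
    gt48_isolate_effects: tuple = (-0.45, -0.15, 0.15, 0.45)
    kgd_isolate_effects: tuple = (0.45, -0.45, 0.15, -0.15)
    gt48_medium_effect: float = 0.2
    kgd_medium_effect: float = 0.2
    interaction_sd: float = 0.1
    replicate_sd: float = 0.2

    # secondary marker candidates
    gt2_base: float = 5.0
    gt2_coupling: float = 0.3  # on centered ln mu
    gt2_noise_sd: float = 0.7
    idh_base: float = 5.4
    idh_noise_sd: float = 0.6
    gs_base: float = 5.0
    gs_isolate_effects: tuple = (0.4, -0.2, 0.2, -0.4)
    gs_poor_effect: float = 1.0  # up-regulation in N-poor medium
    gs_noise_sd: float = 0.3

    # background enzyme classes
    background_ln_range: tuple = (2.6, 6.0)
    background_sample_sd: float = 0.3
    weak_fraction: float = 0.3  # fraction weakly coupled to ln mu (half +, half -)
    weak_coupling: float = 0.15

    # culture design
    b0_range_mg: tuple = (1.5, 4.5)
    target_ln_growth: float = 2.0  # harvest when ln(Bt/B0) reaches this
    t_min_days: float = 3.0
    t_max_days: float = 30.0

    n_failed_samples: int = 10
    count_noise: str = "poisson"  # "poisson", "nb" or "none"
    nb_dispersion: float = 0.1  # only for count_noise="nb"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_isolates < 1 or self.n_media != 2 or self.n_replicates < 1:
            raise ValueError("design must have >=1 isolate, exactly 2 media, >=1 replicate")
        if self.n_ec_classes < len(MARKER_ECS):
            raise ValueError("n_ec_classes must cover the marker classes")
        if self.n_genes < 3 * self.n_ec_classes // 2 + len(MARKER_ECS):
            raise ValueError("n_genes too small for the requested EC classes")
        if self.sigma1 < 0 or self.sigma2 < 0:
            raise ValueError("sigmas must be >= 0")
        if len(self.gt48_isolate_effects) != self.n_isolates:
            raise ValueError("gt48_isolate_effects length must equal n_isolates")
        if len(self.kgd_isolate_effects) != self.n_isolates:
            raise ValueError("kgd_isolate_effects length must equal n_isolates")
        if self.count_noise not in {"poisson", "nb", "none"}:
            raise ValueError("count_noise must be 'poisson', 'nb' or 'none'")

    @property
    def n_samples(self) -> int:
        return self.n_isolates * self.n_media * self.n_replicates


@dataclass
class SyntheticTruth:
    """Ground-truth ledger for one generated study."""

    samples: pd.DataFrame  # sample_id, mu, qco2, cue, ln_gt48, ln_kgd
    ec_rpkm: pd.DataFrame  # true EC x sample RPKM
    marker_ecs: dict[str, str]
    marker_genes: dict[str, list[str]]
    usable_samples: list[str]
    failed_samples: list[str]
    seed: int


class SyntheticStudy(NamedTuple):
    """Bundle returned by :func:`generate_study` (unpackable 5-tuple)."""

    metadata: pd.DataFrame
    phenotypes: pd.DataFrame
    counts: CountMatrix
    annotation: GeneAnnotation
    truth: SyntheticTruth


def invert_physiology(
    mu: float,
    qco2: float,
    B0: float,
    t: float,
    constants: PhysioConstants | None = None,
    sample_id: str = "sample",
) -> PhenotypeRecord:
    """Construct the raw measurements that yield given (mu, qCO2).

    Bt = B0 * e^(mu t) and delta_co2 is chosen so that the closed-loop
    CO2 conversion divided by harvest biomass carbon equals qCO2.  The
    algebraic inverse of the flux calculations: compute_fluxes on the
    result recovers (mu, qCO2) exactly up to floating point.
    """
    if B0 <= 0 or t <= 0:
        raise ValueError("B0 and t must be > 0")
    if qco2 < 0:
        raise ValueError("qco2 must be >= 0")
    c = constants or PhysioConstants()
    Bt = B0 * float(np.exp(mu * t))
    respiration = qco2 * biomass_carbon(Bt, c)
    per_ppm = co2_to_respiration(1.0, c)  # mmol C/day per ppm
    delta = respiration / per_ppm
    if delta < 0:
        raise ValueError("parameters imply a negative CO2 rise")
    return PhenotypeRecord(sample_id=sample_id, B0=B0, Bt=Bt, t=t, delta_co2=delta)


def generate_counts(
    true_rpkm: pd.DataFrame,
    gene_lengths: pd.Series,
    library_sizes: pd.Series,
    rng: np.random.Generator | int,
    noise: str = "poisson",
    nb_dispersion: float = 0.1,
) -> CountMatrix:
    """Convert true per-gene RPKM to an integer count table.

    Expected count[g, s] = rpkm[g, s] * length_kb[g] * library[s] / 1e6;
    integer counts are drawn Poisson around the expectation, negative
    binomial with the given dispersion (var = m + dispersion * m^2), or
    rounded deterministically in noise-free mode.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if (gene_lengths <= 0).any() or (library_sizes <= 0).any():
        raise ValueError("gene lengths and library sizes must be > 0")
    length_kb = gene_lengths.reindex(true_rpkm.index).to_numpy(dtype=float) / 1e3
    lib = library_sizes.reindex(true_rpkm.columns).to_numpy(dtype=float)
    expected = true_rpkm.to_numpy(dtype=float) * length_kb[:, None] * lib[None, :] / 1e6
    if noise == "none":
        counts = np.rint(expected).astype(np.int64)
    elif noise == "poisson":
        counts = rng.poisson(expected).astype(np.int64)
    elif noise == "nb":
        # gamma-Poisson mixture: shape 1/disp, scale disp * m
        shape = 1.0 / nb_dispersion
        lam = rng.gamma(shape, nb_dispersion * expected)
        counts = rng.poisson(lam).astype(np.int64)
    else:
        raise ValueError(f"unknown noise mode {noise!r}")
    cdf = pd.DataFrame(counts, index=true_rpkm.index, columns=true_rpkm.columns)
    return CountMatrix(counts=cdf, gene_lengths=gene_lengths.reindex(true_rpkm.index))


def _background_ec_ids(n: int) -> list[str]:
    """Deterministic synthetic EC identifiers disjoint from the markers."""
    out = []
    i = 0
    while len(out) < n:
        ec = f"{7 + i % 3}.{1 + (i // 3) % 20}.{1 + (i // 60) % 20}.{1 + i // 1200}"
        out.append(ec)
        i += 1
    return out


def _assign_genes(config: StudyConfig, rng: np.random.Generator):
    """Assign genes to EC classes; returns (annotation, gene->weights, ec list)."""
    n_bg = config.n_ec_classes - len(MARKER_ECS)
    ec_ids = list(MARKER_ECS.values()) + _background_ec_ids(n_bg)
    gene_ids = [f"g{i:05d}" for i in range(config.n_genes)]
    annot: dict[str, list[str]] = {}
    members: dict[str, list[str]] = {}
    cursor = 0
    for ec in ec_ids:
        k = int(rng.integers(1, 4))  # 1-3 paralogs per class
        genes = gene_ids[cursor : cursor + k]
        cursor += k
        members[ec] = genes
        for g in genes:
            annot.setdefault(g, []).append(ec)
    # remaining genes are unannotated background
    unannotated = gene_ids[cursor:]
    weights = {
        ec: rng.dirichlet(np.ones(len(genes))) for ec, genes in members.items()
    }
    return GeneAnnotation(annot), members, weights, ec_ids, gene_ids, unannotated


def generate_study(config: StudyConfig | None = None) -> SyntheticStudy:
    """Generate one complete synthetic study.

    Returns metadata, phenotypes, counts, annotation and the ground-truth
    ledger.  The same config (including seed) yields bit-identical
    output.
    """
    cfg = config or StudyConfig()
    rng = np.random.default_rng(cfg.seed)
    constants = PhysioConstants()

    isolates = [f"iso{i + 1}" for i in range(cfg.n_isolates)]
    media = ["poor", "rich"]
    rows = []
    for i, iso in enumerate(isolates):
        for m, med in enumerate(media):
            for r in range(cfg.n_replicates):
                rows.append(
                    {
                        "sample_id": f"{iso}_{med}_r{r + 1}",
                        "isolate": iso,
                        "medium": med,
                        "replicate": r + 1,
                        "_iso_idx": i,
                        "_med_sign": -0.5 if med == "poor" else 0.5,
                    }
                )
    meta = pd.DataFrame(rows)
    n = len(meta)
    iso_idx = meta["_iso_idx"].to_numpy()
    med_sign = meta["_med_sign"].to_numpy()
    poor = (meta["medium"] == "poor").to_numpy().astype(float)

    def cell_interaction() -> np.ndarray:
        eff = rng.normal(0.0, cfg.interaction_sd, size=(cfg.n_isolates, 2))
        med_idx = (med_sign > 0).astype(int)
        return eff[iso_idx, med_idx]

    ln_gt48 = (
        cfg.gt48_base
        + np.asarray(cfg.gt48_isolate_effects)[iso_idx]
        + cfg.gt48_medium_effect * med_sign
        + cell_interaction()
        + rng.normal(0.0, cfg.replicate_sd, n)
    )
    ln_kgd = (
        cfg.kgd_base
        + np.asarray(cfg.kgd_isolate_effects)[iso_idx]
        + cfg.kgd_medium_effect * med_sign
        + cell_interaction()
        + rng.normal(0.0, cfg.replicate_sd, n)
    )
    eps1 = rng.normal(0.0, cfg.sigma1, n) if cfg.sigma1 > 0 else np.zeros(n)
    eps2 = rng.normal(0.0, cfg.sigma2, n) if cfg.sigma2 > 0 else np.zeros(n)
    ln_mu = cfg.alpha1 + cfg.beta1 * ln_gt48 + eps1
    ln_q = cfg.alpha2 + cfg.beta2 * ln_kgd + eps2
    ln_mu_c = ln_mu - ln_mu.mean()

    # secondary candidates and background classes (EC-level ln RPKM)
    ln_gt2 = cfg.gt2_base + cfg.gt2_coupling * ln_mu_c + rng.normal(0, cfg.gt2_noise_sd, n)
    ln_idh_nad = cfg.idh_base + rng.normal(0, cfg.idh_noise_sd, n)
    ln_idh_nadp = cfg.idh_base - 0.1 + rng.normal(0, cfg.idh_noise_sd, n)
    ln_gs = (
        cfg.gs_base
        + np.asarray(cfg.gs_isolate_effects)[iso_idx % len(cfg.gs_isolate_effects)]
        + cfg.gs_poor_effect * poor
        + rng.normal(0, cfg.gs_noise_sd, n)
    )

    annotation, members, weights, ec_ids, gene_ids, unannotated = _assign_genes(cfg, rng)
    n_bg = cfg.n_ec_classes - len(MARKER_ECS)
    bg_ids = ec_ids[len(MARKER_ECS):]
    bg_base = rng.uniform(*cfg.background_ln_range, n_bg)
    # a fraction of background classes tracks growth weakly, half each sign,
    # so genome-wide ranking is nontrivial but depth totals stay balanced
    n_weak = int(round(cfg.weak_fraction * n_bg))
    coupling = np.zeros(n_bg)
    coupling[: n_weak // 2] = cfg.weak_coupling
    coupling[n_weak // 2 : n_weak] = -cfg.weak_coupling
    rng.shuffle(coupling)
    ln_bg = (
        bg_base[:, None]
        + coupling[:, None] * ln_mu_c[None, :]
        + rng.normal(0.0, cfg.background_sample_sd, (n_bg, n))
    )

    ec_ln = np.vstack(
        [ln_gt48, ln_gt2, ln_kgd, ln_idh_nad, ln_idh_nadp, ln_gs, ln_bg]
    )
    ec_order = [
        MARKER_ECS["gt48"],
        MARKER_ECS["gt2"],
        MARKER_ECS["kgd"],
        MARKER_ECS["idh_nad"],
        MARKER_ECS["idh_nadp"],
        MARKER_ECS["gs"],
    ] + bg_ids
    ec_rpkm = pd.DataFrame(np.exp(ec_ln), index=ec_order, columns=meta["sample_id"])

    # distribute EC-level RPKM over member genes; unannotated genes get
    # their own lognormal expression (they only influence library totals)
    gene_rpkm = pd.DataFrame(0.0, index=gene_ids, columns=meta["sample_id"])
    for ec, genes in members.items():
        w = weights[ec]
        gene_rpkm.loc[genes] = w[:, None] * ec_rpkm.loc[ec].to_numpy()[None, :]
    if unannotated:
        base = rng.uniform(1.0, 4.5, len(unannotated))
        noise = rng.normal(0.0, cfg.background_sample_sd, (len(unannotated), n))
        gene_rpkm.loc[unannotated] = np.exp(base[:, None] + noise)

    gene_lengths = pd.Series(
        np.clip(np.rint(np.exp(rng.normal(np.log(1500.0), 0.4, cfg.n_genes))), 200, None),
        index=gene_ids,
        name="length_bp",
    )

    # RPKM is self-consistent only if sum_g rpkm * length_kb = 1e6 per
    # sample (total counts equal the depth denominator).  A block of
    # highly expressed unannotated genes (ribosomal-protein-like bulk
    # transcripts) absorbs the per-sample remainder so the emitted count
    # table reproduces the planted RPKM without a per-sample scale shift.
    n_filler = min(50, len(unannotated))
    if n_filler == 0:
        raise ValueError("config leaves no unannotated genes for the expression bulk")
    filler = unannotated[-n_filler:]
    len_kb = gene_lengths.to_numpy(dtype=float) / 1e3
    budget = 1e6 - (gene_rpkm.to_numpy() * len_kb[:, None]).sum(axis=0)
    if (budget <= 0).any():
        raise ValueError("planted expression exceeds the per-sample RPKM budget")
    fw = rng.dirichlet(np.ones(n_filler))
    filler_len_kb = gene_lengths.loc[filler].to_numpy(dtype=float) / 1e3
    gene_rpkm.loc[filler] = (fw[:, None] * budget[None, :]) / filler_len_kb[:, None]

    mu_ln_lib = np.log(cfg.library_size_mean) - 0.5 * cfg.library_size_dispersion**2
    library_sizes = pd.Series(
        np.exp(rng.normal(mu_ln_lib, cfg.library_size_dispersion, n)),
        index=meta["sample_id"],
        name="library_size",
    )
    counts = generate_counts(
        gene_rpkm, gene_lengths, library_sizes, rng,
        noise=cfg.count_noise, nb_dispersion=cfg.nb_dispersion,
    )

    if cfg.count_noise == "none":
        # re-anchor the planted power laws on the realized count table so
        # the noiseless round trip (generate -> pipeline -> fit) is exact
        realized = aggregate_by_ec(rpkm_normalize(counts), annotation)
        ln_gt48 = np.log(realized.loc[MARKER_ECS["gt48"]].to_numpy())
        ln_kgd = np.log(realized.loc[MARKER_ECS["kgd"]].to_numpy())
        ln_mu = cfg.alpha1 + cfg.beta1 * ln_gt48 + eps1
        ln_q = cfg.alpha2 + cfg.beta2 * ln_kgd + eps2
        ec_rpkm = realized.reindex(ec_order)

    mu = np.exp(ln_mu)
    qco2 = np.exp(ln_q)
    cue = mu / (mu + qco2)

    # culture phenotypes: harvest when ln(Bt/B0) reaches the target, as
    # when culturing stops at a fixed substrate-consumption fraction
    b0 = rng.uniform(*cfg.b0_range_mg, n)
    t = np.clip(cfg.target_ln_growth / mu, cfg.t_min_days, cfg.t_max_days)
    phen_rows = []
    for k, sid in enumerate(meta["sample_id"]):
        rec = invert_physiology(mu[k], qco2[k], b0[k], t[k], constants, sample_id=sid)
        phen_rows.append(
            {
                "sample_id": sid,
                "B0_mg": rec.B0,
                "Bt_mg": rec.Bt,
                "t_days": rec.t,
                "delta_co2_ppm": rec.delta_co2,
            }
        )
    phenotypes = pd.DataFrame(phen_rows)

    # sequencing dropout: some libraries fail, shrinking the usable set
    failed_idx = rng.choice(n, size=cfg.n_failed_samples, replace=False)
    failed = sorted(meta["sample_id"].iloc[failed_idx])
    usable = [s for s in meta["sample_id"] if s not in set(failed)]
    counts = CountMatrix(
        counts=counts.counts.loc[:, usable], gene_lengths=counts.gene_lengths
    )

    truth = SyntheticTruth(
        samples=pd.DataFrame(
            {
                "sample_id": meta["sample_id"],
                "mu": mu,
                "qco2": qco2,
                "cue": cue,
                "ln_gt48": ln_gt48,
                "ln_kgd": ln_kgd,
            }
        ),
        ec_rpkm=ec_rpkm,
        marker_ecs=dict(MARKER_ECS),
        marker_genes={name: members[ec] for name, ec in MARKER_ECS.items()},
        usable_samples=usable,
        failed_samples=failed,
        seed=cfg.seed,
    )
    metadata = meta.drop(columns=["_iso_idx", "_med_sign"])
    return SyntheticStudy(metadata, phenotypes, counts, annotation, truth)


def analyze_study(study: SyntheticStudy, rpkm_threshold: float = 10.0) -> dict:
    """Run the analysis chain on one generated study (in memory).

    Fluxes from phenotypes, RPKM + EC aggregation + filter, the growth and
    respiration marker fits, the genome-wide growth screen rank of the
    planted growth marker, and the index-vs-measured-CUE evaluation.
    """
    from .cue_index import build_index, cue_gene, evaluate_index
    from .expression import filter_min_expression
    from .markers import correlation_screen, fit_loglog, marker_rank
    from .physiology import compute_fluxes

    records = [
        PhenotypeRecord(r.sample_id, r.B0_mg, r.Bt_mg, r.t_days, r.delta_co2_ppm)
        for r in study.phenotypes.itertuples()
    ]
    fluxes = {f.sample_id: f for f in compute_fluxes(records)}
    usable = [s for s in study.counts.sample_ids if not fluxes[s].qc_flags]
    ec = aggregate_by_ec(rpkm_normalize(study.counts), study.annotation)
    filtered = filter_min_expression(ec, rpkm_threshold)
    mu = pd.Series({s: fluxes[s].mu for s in usable})
    qco2 = pd.Series({s: fluxes[s].qco2 for s in usable})
    cue = pd.Series({s: fluxes[s].cue for s in usable})

    gt48_ec, kgd_ec = MARKER_ECS["gt48"], MARKER_ECS["kgd"]
    growth = fit_loglog(ec.loc[gt48_ec, usable], mu, "mu", gt48_ec)
    resp = fit_loglog(ec.loc[kgd_ec, usable], qco2, "qco2", kgd_ec)
    ranking = correlation_screen(filtered.loc[:, usable], mu, "mu")
    index = build_index(growth, resp)
    cue_idx = [
        cue_gene(index, g, k)
        for g, k in zip(ec.loc[gt48_ec, usable], ec.loc[kgd_ec, usable])
    ]
    evaluation = evaluate_index(cue_idx, cue.to_numpy())
    return {
        "n_usable": len(usable),
        "n_retained": len(filtered),
        "growth_model": growth,
        "resp_model": resp,
        "gt48_rank": marker_rank(ranking, gt48_ec) if gt48_ec in set(filtered.index) else None,
        "index_evaluation": evaluation,
        "compact_constant": index.compact_constant,
    }


def marker_recovery_simulation(
    n_replicates: int = 200,
    base_seed: int = 0,
    config: StudyConfig | None = None,
) -> pd.DataFrame:
    """Repeatedly generate and analyze studies; one row per replicate.

    Columns: beta1, alpha1, r2_growth, beta2, r2_resp, gt48_rank,
    n_retained, index_slope, index_r2.  Replicate i uses seed
    (base_seed + i) mod 2^31.
    """
    base = config or StudyConfig()
    rows = []
    for i in range(n_replicates):
        seed = (base_seed + i) % 2**31
        study = generate_study(
            StudyConfig(**{**base.__dict__, "seed": seed})
        )
        res = analyze_study(study)
        rows.append(
            {
                "seed": seed,
                "beta1": res["growth_model"].beta,
                "alpha1": res["growth_model"].alpha,
                "r2_growth": res["growth_model"].r2,
                "beta2": res["resp_model"].beta,
                "r2_resp": res["resp_model"].r2,
                "gt48_rank": res["gt48_rank"],
                "n_retained": res["n_retained"],
                "index_slope": res["index_evaluation"].beta,
                "index_r2": res["index_evaluation"].r2,
            }
        )
    return pd.DataFrame(rows)


def tiny_fixture() -> SyntheticStudy:
    """A 3-gene / 4-sample worked example with hand-checkable numbers.

    Counts are chosen so each sample totals exactly one million reads and
    gene lengths are round fractions of a kilobase, making the RPKM and
    EC aggregation arithmetic verifiable by hand.
    """
    samples = ["s1", "s2", "s3", "s4"]
    genes = ["gA", "gB", "gC"]
    counts = pd.DataFrame(
        [
            [10, 20, 40, 10],
            [30, 30, 30, 30],
            [999_960, 999_950, 999_930, 999_960],
        ],
        index=genes,
        columns=samples,
    )
    lengths = pd.Series([500.0, 2000.0, 1000.0], index=genes, name="length_bp")
    annot = GeneAnnotation(
        {"gA": ["2.4.1.34"], "gB": ["2.4.1.34", "1.2.4.2"], "gC": []}
    )
    cm = CountMatrix(counts=counts, gene_lengths=lengths)
    meta = pd.DataFrame(
        {
            "sample_id": samples,
            "isolate": ["iso1", "iso1", "iso2", "iso2"],
            "medium": ["poor", "rich", "poor", "rich"],
            "replicate": [1, 1, 1, 1],
        }
    )
    phen = pd.DataFrame(
        {
            "sample_id": samples,
            "B0_mg": [2.0, 2.0, 2.0, 2.0],
            "Bt_mg": [8.0, 12.0, 6.0, 10.0],
            "t_days": [10.0, 10.0, 10.0, 10.0],
            "delta_co2_ppm": [50.0, 60.0, 40.0, 55.0],
        }
    )
    truth = SyntheticTruth(
        samples=pd.DataFrame({"sample_id": samples}),
        ec_rpkm=pd.DataFrame(),
        marker_ecs=dict(MARKER_ECS),
        marker_genes={"gt48": ["gA", "gB"], "kgd": ["gB"]},
        usable_samples=samples,
        failed_samples=[],
        seed=0,
    )
    return SyntheticStudy(meta, phen, cm, annot, truth)
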