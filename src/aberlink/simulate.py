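"""Seeded multi-modal data generator with planted ground truth.

Emulates the statistical structure the pipeline is built for: per-sample
chromosome CNV states with probe noise and planted breakpoints, cis
targets tracking their local copy number, trans targets driven by other
chromosomes' CNVs, mutation effectors shifting target means, methylation
clusters and microRNA effectors repressing targets, survival times whose
hazard follows planted module activities, and subtype / methylator-
phenotype labels assigned from those activities.

The generator first lays down a *blueprint* (gene coordinates, planted
breakpoints, effector-target wiring) from the seed, then draws sample-
level data from it; external validation cohorts re-draw new samples from
the same blueprint, optionally attenuating aberration prevalence in the
comparison (non-GBM) group.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .datamodel import SUBTYPES, ClinicalRecord, OmicsDataset


@dataclass
class SimConfig:
    """Generator parameters; defaults are the package's study conditions."""

    n_samples: int = 120
    n_genes: int = 400
    n_chromosomes: int = 4
    probes_per_chrom: int = 80
    chrom_length_bp: int = 120_000_000

    # CNV layer: per-segment copy state in {-1, 0, +1}, probe log-ratio
    # magnitude 0.5 per state with Gaussian probe noise
    breakpoints_per_chrom: int = 1
    p_gain: float = 0.2
    p_loss: float = 0.2
    probe_noise_sd: float = 0.3
    state_magnitude: float = 0.5

    # expression coupling: planted shifts on the raw expression scale
    effect_shift: float = 0.8
    expr_noise_sd: float = 0.4
    cis_target_fraction: float = 0.4
    n_trans_targets: int = 25          # per trans-driver chromosome

    # discrete / epigenetic effectors
    n_mutation_effectors: int = 3
    mutation_prevalence: float = 0.1
    targets_per_mutation: int = 15     # beyond the mutated gene itself
    n_meth_clusters: int = 2
    meth_cluster_size: int = 4
    meth_prevalence: float = 0.3
    targets_per_meth: int = 25         # beyond the methylated genes themselves
    n_mirna: int = 6
    mirna_cluster_size: int = 2
    mirna_prevalence: float = 0.3
    targets_per_mirna: int = 20
    n_snps: int = 5

    # survival layer: exponential times, hazard scaled by module activities
    baseline_survival_days: float = 400.0
    censoring_fraction: float = 0.3
    max_followup_days: float = 3000.0

    def validate(self) -> None:
        planted = (
            int(np.ceil(self.n_genes * self.cis_target_fraction))
            + self.n_trans_targets * 2
            + self.n_mutation_effectors * (self.targets_per_mutation + 1)
            + self.n_meth_clusters * (self.targets_per_meth + self.meth_cluster_size)
            + 2 * self.targets_per_mirna
        )
        if planted > self.n_genes:
            raise ValueError(
                f"config plants ~{planted} targets but only {self.n_genes} genes exist"
            )

    def scaled(self, factor: float) -> "SimConfig":
        """A proportionally smaller instance of the same study conditions
        (sample count and per-effector target counts scaled; effect sizes,
        prevalences and noise untouched)."""
        return SimConfig(
            n_samples=max(30, int(self.n_samples * factor)),
            n_genes=max(80, int(self.n_genes * factor)),
            n_trans_targets=max(5, int(self.n_trans_targets * factor)),
            targets_per_mutation=max(4, int(self.targets_per_mutation * factor)),
            targets_per_meth=max(5, int(self.targets_per_meth * factor)),
            targets_per_mirna=max(4, int(self.targets_per_mirna * factor)),
            probes_per_chrom=max(30, int(self.probes_per_chrom * factor)),
        )


@dataclass
class GroundTruth:
    """Planted structure serialized alongside every generated dataset."""

    config: dict
    seed: int
    breakpoints: dict[str, list[int]]
    #: list of dicts: effector_key, effector_type, target, sign, level
    planted_edges: list[dict]
    effector_clusters: dict[str, list[str]]
    survival_betas: dict[str, float]
    blueprint: dict = field(repr=False, default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(**d)

    def planted_edge_set(self) -> set[tuple[str, str, str, int]]:
        return {
            (e["effector_key"], e["target"], e["sign"], e["level"])
            for e in self.planted_edges
        }


def _blueprint(config: SimConfig, rng: np.random.Generator) -> dict:
    """Lay down the planted structure (no sample-level randomness yet)."""
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    genes = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    per_chrom = config.n_genes // config.n_chromosomes
    gene_chrom, gene_pos = {}, {}
    for ci, chrom in enumerate(chroms):
        members = genes[ci * per_chrom:(ci + 1) * per_chrom]
        pos = np.sort(rng.uniform(1e6, config.chrom_length_bp - 1e6, len(members)))
        for g, p in zip(members, pos):
            gene_chrom[g] = chrom
            gene_pos[g] = (int(p), int(p) + 10_000)
    # leftover genes (if n_genes not divisible) go to the last chromosome
    for g in genes[config.n_chromosomes * per_chrom:]:
        p = float(rng.uniform(1e6, config.chrom_length_bp - 1e6))
        gene_chrom[g] = chroms[-1]
        gene_pos[g] = (int(p), int(p) + 10_000)

    probe_spacing = config.chrom_length_bp // config.probes_per_chrom
    breakpoints = {
        chrom: sorted(
            int(b) for b in rng.choice(
                np.arange(config.probes_per_chrom // 4, 3 * config.probes_per_chrom // 4),
                size=config.breakpoints_per_chrom, replace=False,
            )
        )
        for chrom in chroms
    }

    pool = list(genes)
    rng.shuffle(pool)

    def take(n: int) -> list[str]:
        taken, pool[:] = pool[:n], pool[n:]
        return taken

    # cis targets: a fraction of each chromosome's genes track local copy number
    cis_targets = {
        chrom: sorted(
            g for g in genes if gene_chrom[g] == chrom
            and rng.random() < config.cis_target_fraction
        )
        for chrom in chroms
    }
    for chrom in chroms:
        for g in cis_targets[chrom]:
            if g in pool:
                pool.remove(g)

    # trans drivers: chr1 acts positively, chr2 negatively on other-chromosome genes
    trans = {}
    for chrom, sign in ((chroms[0], "+"), (chroms[1], "-")):
        others = [g for g in pool if gene_chrom[g] != chrom]
        chosen = sorted(rng.choice(others, size=config.n_trans_targets, replace=False))
        trans[chrom] = (sign, chosen)
        for g in chosen:
            pool.remove(g)

    # mutation effectors: the gene itself plus random other targets, random sign
    mutations = {}
    for _ in range(config.n_mutation_effectors):
        eff = take(1)[0]
        sign = "+" if rng.random() < 0.5 else "-"
        others = sorted(rng.choice(pool, size=config.targets_per_mutation, replace=False))
        for g in others:
            pool.remove(g)
        mutations[eff] = (sign, others)

    # methylation clusters: member genes silenced, plus non-local targets repressed
    meth_clusters = {}
    for mi in range(config.n_meth_clusters):
        members = sorted(take(config.meth_cluster_size))
        others = sorted(rng.choice(pool, size=config.targets_per_meth, replace=False))
        for g in others:
            pool.remove(g)
        meth_clusters[f"methcl{mi}"] = (members, others)

    # microRNA effector clusters (two co-expressed miRNAs per cluster) repress targets
    mirnas = [f"mir{i + 1:02d}" for i in range(config.n_mirna)]
    mirna_clusters = {}
    for mi in range(2):
        members = mirnas[mi * config.mirna_cluster_size:(mi + 1) * config.mirna_cluster_size]
        targets = sorted(rng.choice(pool, size=config.targets_per_mirna, replace=False))
        for g in targets:
            pool.remove(g)
        mirna_clusters[f"mircl{mi}"] = (members, targets)

    snps = [f"rs{i + 1:04d}" for i in range(config.n_snps)]

    return {
        "chroms": chroms,
        "genes": genes,
        "gene_chrom": gene_chrom,
        "gene_pos": {g: list(v) for g, v in gene_pos.items()},
        "probe_spacing": probe_spacing,
        "breakpoints": breakpoints,
        "cis_targets": cis_targets,
        "trans": {c: [s, list(t)] for c, (s, t) in trans.items()},
        "mutations": {e: [s, list(t)] for e, (s, t) in mutations.items()},
        "meth_clusters": {k: [list(m), list(t)] for k, (m, t) in meth_clusters.items()},
        "mirnas": mirnas,
        "mirna_clusters": {k: [list(m), list(t)] for k, (m, t) in mirna_clusters.items()},
        "snps": snps,
    }


def _planted_edges(bp: dict) -> list[dict]:
    edges: list[dict] = []
    for chrom, targets in bp["cis_targets"].items():
        for g in targets:
            edges.append({"effector_key": f"cnv:{chrom}", "effector_type": "cis_cnv",
                          "target": g, "sign": "+", "level": 1})
    for chrom, (sign, targets) in ((c, tuple(v)) for c, v in bp["trans"].items()):
        for g in targets:
            edges.append({"effector_key": f"cnv:{chrom}", "effector_type": "trans_cnv",
                          "target": g, "sign": sign,
                          "level": 2 if sign == "+" else 3})
    for eff, (sign, targets) in ((e, tuple(v)) for e, v in bp["mutations"].items()):
        edges.append({"effector_key": f"mut:{eff}", "effector_type": "mutation",
                      "target": eff, "sign": "+", "level": 1})
        for g in targets:
            edges.append({"effector_key": f"mut:{eff}", "effector_type": "mutation",
                          "target": g, "sign": sign, "level": 2})
    for key, (members, targets) in ((k, tuple(v)) for k, v in bp["meth_clusters"].items()):
        for g in members:
            edges.append({"effector_key": f"meth:{key}", "effector_type": "methylation",
                          "target": g, "sign": "-", "level": 1})
        for g in targets:
            edges.append({"effector_key": f"meth:{key}", "effector_type": "methylation",
                          "target": g, "sign": "-", "level": 2})
    for key, (members, targets) in ((k, tuple(v)) for k, v in bp["mirna_clusters"].items()):
        for g in targets:
            edges.append({"effector_key": f"mir:{key}", "effector_type": "mirna",
                          "target": g, "sign": "-", "level": 4})
    return edges


def _draw_cohort(bp: dict, config: SimConfig, rng: np.random.Generator,
                 n_samples: int, prevalence_scale: np.ndarray):
    """Draw sample-level data from a blueprint.

    prevalence_scale is a per-sample multiplier in [0, 1] on aberration
    prevalence (1 = full disease prevalence; used to attenuate the
    comparison group of external cohorts).
    """
    chroms = bp["chroms"]
    genes = bp["genes"]
    spacing = bp["probe_spacing"]
    n_probes = config.probes_per_chrom

    # --- CNV states per (chromosome, segment, sample)
    seg_states: dict[str, np.ndarray] = {}
    probe_rows, probe_ids, probe_bed_rows = [], [], []
    for chrom in chroms:
        edges = [0, *bp["breakpoints"][chrom], n_probes]
        n_seg = len(edges) - 1
        states = np.zeros((n_seg, n_samples), dtype=int)
        u = rng.random((n_seg, n_samples))
        p_gain = config.p_gain * prevalence_scale
        p_loss = config.p_loss * prevalence_scale
        states[u < p_gain] = 1
        states[u > 1 - p_loss] = -1
        seg_states[chrom] = states
        for pi in range(n_probes):
            seg_idx = int(np.searchsorted(np.asarray(edges[1:-1]), pi, side="right"))
            vals = (config.state_magnitude * states[seg_idx]
                    + rng.normal(0, config.probe_noise_sd, n_samples))
            pid = f"{chrom}_p{pi:03d}"
            probe_ids.append(pid)
            probe_rows.append(vals)
            probe_bed_rows.append((pid, chrom, pi * spacing, pi * spacing + 60))

    def seg_state_at(chrom: str, pos_bp: int) -> np.ndarray:
        edges = [0, *bp["breakpoints"][chrom], n_probes]
        pi = min(pos_bp // spacing, n_probes - 1)
        seg_idx = int(np.searchsorted(np.asarray(edges[1:-1]), pi, side="right"))
        return seg_states[chrom][seg_idx]

    # --- latent effector activities
    mut_ind = {
        eff: (rng.random(n_samples) < config.mutation_prevalence * prevalence_scale)
        .astype(int)
        for eff in bp["mutations"]
    }
    meth_latent = {
        key: (rng.random(n_samples) < config.meth_prevalence * prevalence_scale)
        .astype(int)
        for key in bp["meth_clusters"]
    }
    mir_latent = {
        key: (rng.random(n_samples) < config.mirna_prevalence * prevalence_scale)
        .astype(int)
        for key in bp["mirna_clusters"]
    }

    # --- mRNA expression
    shift, noise = config.effect_shift, config.expr_noise_sd
    expr = pd.DataFrame(
        rng.normal(0, 1.0, (len(genes), n_samples)), index=genes,
    )
    for chrom, targets in bp["cis_targets"].items():
        for g in targets:
            s = seg_state_at(chrom, bp["gene_pos"][g][0])
            expr.loc[g] = shift * s + rng.normal(0, noise, n_samples)
    for chrom, (sign, targets) in ((c, tuple(v)) for c, v in bp["trans"].items()):
        sgn = 1.0 if sign == "+" else -1.0
        drv = seg_states[chrom][0]
        for g in targets:
            expr.loc[g] = sgn * shift * drv + rng.normal(0, noise, n_samples)
    for eff, (sign, targets) in ((e, tuple(v)) for e, v in bp["mutations"].items()):
        sgn = 1.0 if sign == "+" else -1.0
        m = mut_ind[eff]
        expr.loc[eff] = shift * m + rng.normal(0, noise, n_samples)
        for g in targets:
            expr.loc[g] = sgn * shift * m + rng.normal(0, noise, n_samples)
    for key, (members, targets) in ((k, tuple(v)) for k, v in bp["meth_clusters"].items()):
        h = meth_latent[key]
        for g in [*members, *targets]:
            expr.loc[g] = -shift * h + rng.normal(0, noise, n_samples)
    for key, (members, targets) in ((k, tuple(v)) for k, v in bp["mirna_clusters"].items()):
        u = mir_latent[key]
        for g in targets:
            expr.loc[g] = -shift * u + rng.normal(0, noise, n_samples)

    # --- other modality matrices
    meth_rows = {}
    for key, (members, _t) in ((k, tuple(v)) for k, v in bp["meth_clusters"].items()):
        for g in members:
            meth_rows[g] = meth_latent[key] + rng.normal(0, 0.3, n_samples)
    mirna_expr = pd.DataFrame(
        rng.normal(0, 1.0, (len(bp["mirnas"]), n_samples)), index=bp["mirnas"],
    )
    for key, (members, _t) in ((k, tuple(v)) for k, v in bp["mirna_clusters"].items()):
        for m in members:
            mirna_expr.loc[m] = mir_latent[key] + rng.normal(0, 0.3, n_samples)

    mut_mat = {}
    for eff in bp["mutations"]:
        calls = np.full(n_samples, "wildtype", dtype=object)
        carriers = np.flatnonzero(mut_ind[eff])
        kinds = rng.choice(["missense", "nonsense"], size=len(carriers))
        calls[carriers] = kinds
        mut_mat[eff] = calls

    snp_mat = {
        s: rng.choice(["0", "1", "2"], size=n_samples, p=[0.49, 0.42, 0.09])
        for s in bp["snps"]
    }

    # --- survival coupled to planted module activities
    betas = {
        f"cnv:{chroms[0]}": 0.7,       # trans chr1 gain = worse survival
        f"cnv:{chroms[1]}": 0.5,
        "meth:methcl0": -0.7,          # methylator-phenotype-like: better survival
        f"mut:{next(iter(bp['mutations']))}": 0.5,
    }
    activity = {
        f"cnv:{chroms[0]}": seg_states[chroms[0]][0].astype(float),
        f"cnv:{chroms[1]}": seg_states[chroms[1]][0].astype(float),
        "meth:methcl0": meth_latent["methcl0"].astype(float),
        f"mut:{next(iter(bp['mutations']))}": next(iter(mut_ind.values())).astype(float),
    }
    lp = sum(betas[k] * activity[k] for k in betas)
    rate = np.exp(lp) / config.baseline_survival_days
    times = rng.exponential(1.0 / rate)
    censored = rng.random(n_samples) < config.censoring_fraction
    obs_times = np.where(censored, rng.uniform(0, np.maximum(times, 1e-9)), times)
    obs_times = np.minimum(obs_times, config.max_followup_days)
    events = (~censored & (times <= config.max_followup_days)).astype(int)

    # --- subtype / G-CIMP labels from planted activities
    gcimp = meth_latent["methcl0"]
    score = np.stack([
        activity[f"cnv:{chroms[0]}"],
        -activity[f"cnv:{chroms[1]}"],
        activity[f"mut:{next(iter(bp['mutations']))}"] * 1.5,
        mir_latent["mircl0"].astype(float),
    ])
    subtype_idx = np.argmax(score + rng.normal(0, 0.1, score.shape), axis=0)
    subtypes = [SUBTYPES[i] for i in subtype_idx]

    probe_mat = pd.DataFrame(np.stack(probe_rows), index=probe_ids)
    meth_mat = pd.DataFrame(meth_rows).T if meth_rows else pd.DataFrame()
    return {
        "expr": expr, "probe_mat": probe_mat, "probe_bed": probe_bed_rows,
        "meth": meth_mat, "mirna": mirna_expr,
        "mutation": pd.DataFrame(mut_mat).T, "snp": pd.DataFrame(snp_mat).T,
        "survival_days": obs_times, "event": events,
        "subtype": subtypes, "gcimp": gcimp,
        "betas": betas,
        "latents": {"mut": mut_ind, "meth": meth_latent, "mir": mir_latent,
                    "seg_states": seg_states},
    }


def _gene_bed(bp: dict) -> pd.DataFrame:
    rows = {
        g: {"symbol": g, "chrom": bp["gene_chrom"][g],
            "start": bp["gene_pos"][g][0], "end": bp["gene_pos"][g][1], "strand": "+"}
        for g in bp["genes"]
    }
    ann = pd.DataFrame.from_dict(rows, orient="index")
    ann.index.name = "feature"
    return ann


def _probe_bed_frame(rows) -> pd.DataFrame:
    ann = pd.DataFrame(
        [{"symbol": pid, "chrom": c, "start": s, "end": e, "strand": "+"}
         for pid, c, s, e in rows],
        index=[r[0] for r in rows],
    )
    ann.index.name = "feature"
    return ann


def generate(config: SimConfig | None = None, seed: int = 0):
    """Generate a full multi-modal dataset plus its ground truth.

    Returns ``(OmicsDataset, GroundTruth)``; byte-identical for a fixed
    (config, seed).
    """
    if config is None:
        config = SimConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    bp = _blueprint(config, rng)
    cohort = _draw_cohort(bp, config, rng, config.n_samples,
                          prevalence_scale=np.ones(config.n_samples))
    samples = [f"S{i + 1:03d}" for i in range(config.n_samples)]

    def _named(df: pd.DataFrame) -> pd.DataFrame:
        df = df.copy()
        df.columns = samples
        return df

    clinical = {
        s: ClinicalRecord(
            survival_days=float(cohort["survival_days"][i]),
            event=int(cohort["event"][i]),
            subtype=cohort["subtype"][i],
            gcimp=int(cohort["gcimp"][i]),
        )
        for i, s in enumerate(samples)
    }
    ds = OmicsDataset(
        samples=samples,
        modalities={
            "mrna": _named(cohort["expr"]),
            "mirna": _named(cohort["mirna"]),
            "cnv_probe": _named(cohort["probe_mat"]),
            "methylation": _named(cohort["meth"]),
            "mutation": _named(cohort["mutation"]),
            "snp": _named(cohort["snp"]),
        },
        feature_annotations={
            "mrna": _gene_bed(bp),
            "cnv_probe": _probe_bed_frame(cohort["probe_bed"]),
            "methylation": _gene_bed(bp).loc[list(cohort["meth"].index)],
        },
        clinical=clinical,
    )
    ds.validate()
    clusters = {
        **{k: list(v[0]) for k, v in bp["meth_clusters"].items()},
        **{k: list(v[0]) for k, v in bp["mirna_clusters"].items()},
    }
    truth = GroundTruth(
        config=asdict(config),
        seed=seed,
        breakpoints=bp["breakpoints"],
        planted_edges=_planted_edges(bp),
        effector_clusters=clusters,
        survival_betas=cohort["betas"],
        blueprint=bp,
    )
    return ds, truth


def generate_external(
    truth: GroundTruth,
    seed: int = 1,
    n_samples: int = 100,
    gbm_fraction: float = 0.5,
    attenuation: float = 0.2,
):
    """Draw an expression-only validation cohort from an existing blueprint.

    Returns ``(expr, clinical_frame, group_labels)``: mRNA matrix, a
    clinical frame (survival_days, event) and per-sample "GBM"/"non-GBM"
    labels.  Non-GBM samples carry aberrations at ``attenuation`` times
    the disease prevalence (attenuation 1.0 = no group difference).
    """
    config = SimConfig(**truth.config)
    rng = np.random.default_rng(seed)
    is_gbm = rng.random(n_samples) < gbm_fraction
    scale = np.where(is_gbm, 1.0, attenuation)
    cohort = _draw_cohort(truth.blueprint, config, rng, n_samples, prevalence_scale=scale)
    samples = [f"E{i + 1:03d}" for i in range(n_samples)]
    expr = cohort["expr"].copy()
    expr.columns = samples
    clinical = pd.DataFrame(
        {"survival_days": cohort["survival_days"], "event": cohort["event"]},
        index=samples,
    )
    groups = pd.Series(np.where(is_gbm, "GBM", "non-GBM"), index=samples)
    return expr, clinical, groups
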