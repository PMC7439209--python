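"""End-to-end orchestration: generate -> parcellate -> densities -> networks
-> metrics -> integrate -> asymmetry -> statistics.

Each stage reads the previous stage's on-disk artifacts from a run directory
and writes its own, together with a ``<stage>.done.json`` marker holding a
hash of the configuration and of the upstream markers; re-running a completed
stage with unchanged inputs is a no-op.  All randomness is derived
deterministically from the single global seed, so a re-run from scratch
reproduces byte-identical outputs.

The module also exposes the in-memory fast path (:func:`subject_networks`,
:func:`cohort_analysis`) used by the statistical simulation helpers, which
skips disk round trips entirely.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import data_io
from .density import DensityConfig, subject_densities
from .integration import ai_table, integrate_global, integrate_local
from .metrics import (RandomizationConfig, all_pairs_distances,
                      compute_global_metrics, degree_centrality,
                      nodal_efficiency)
from .network import HemisphericNetwork, SparsityGrid, binarize, build_network
from .parcellation import (DEFAULT_SIZE_FLOOR, TARGET_PER_HEMISPHERE,
                           Parcellation, upsample)
from .synthetic_cohort import (EffectSpec, GeneratorConfig, generate_cohort,
                               generate_surface)

__all__ = [
    "PipelineConfig",
    "STAGES",
    "run_all",
    "run_stage",
    "subject_networks",
    "cohort_analysis",
    "small_world_summary",
    "statistics_tables",
    "global_metric_names",
    "LOCAL_METRICS",
]

logger = logging.getLogger(__name__)

STAGES = ("generate", "parcellate", "densities", "networks", "metrics",
          "integrate", "asymmetry", "stats")

LOCAL_METRICS = ("degree", "E_nodal")


def derive_seed(seed: int, tag: str) -> int:
    """Deterministic per-stage sub-seed (< 2**31) from the global seed."""
    ss = np.random.SeedSequence([int(seed), zlib.crc32(tag.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class PipelineConfig:
    generator: GeneratorConfig = GeneratorConfig()
    density: DensityConfig = DensityConfig()
    sparsity: SparsityGrid = field(default_factory=SparsityGrid)
    randomization: RandomizationConfig | None = RandomizationConfig(n_random=10)
    target_per_hemisphere: int = TARGET_PER_HEMISPHERE
    size_floor: int = DEFAULT_SIZE_FLOOR
    welch: bool = False
    fdr_q: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        self.generator.validate()
        self.density.validate()
        if self.randomization is not None:
            self.randomization.validate()
        if not (0 < self.fdr_q < 1):
            raise ValueError("fdr_q must be in (0, 1)")

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sparsity"] = {"values": list(self.sparsity.values)}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "generator" in d:
            g = dict(d["generator"])
            if "effect_specs" in g:
                g["effect_specs"] = tuple(
                    EffectSpec(**e) if isinstance(e, dict) else e
                    for e in g["effect_specs"]
                )
            for key in ("thickness_mean_range", "age_range", "region_names"):
                if g.get(key) is not None:
                    g[key] = tuple(g[key])
            if isinstance(g.get("within_region_sd"), list):
                g["within_region_sd"] = tuple(g["within_region_sd"])
            d["generator"] = GeneratorConfig(**g)
        if "density" in d:
            d["density"] = DensityConfig(**d["density"])
        if "sparsity" in d:
            s = d["sparsity"]
            if isinstance(s, dict) and "values" in s:
                d["sparsity"] = SparsityGrid(tuple(float(v) for v in s["values"]))
            elif isinstance(s, dict):
                vals = np.round(np.arange(s["min"], s["max"] + s["step"] / 2,
                                          s["step"]), 10)
                d["sparsity"] = SparsityGrid(tuple(float(v) for v in vals))
            else:
                d["sparsity"] = SparsityGrid(tuple(float(v) for v in s))
        if d.get("randomization") is not None:
            d["randomization"] = RandomizationConfig(**d["randomization"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def global_metric_names(config: PipelineConfig) -> list[str]:
    """The global metric set reported by the statistics stage."""
    if config.randomization is not None:
        return ["Cp_norm", "Lp_norm", "sigma", "E_global", "E_local"]
    return ["Lp", "Cp", "E_global", "E_local"]


# ---------------------------------------------------------------------------
# in-memory fast path
# ---------------------------------------------------------------------------

def subject_networks(
    vertex_table: pd.DataFrame,
    parcellation: Parcellation,
    density_config: DensityConfig = DensityConfig(),
    grid: SparsityGrid = SparsityGrid(),
    subject_id: str = "",
) -> dict[str, HemisphericNetwork]:
    """Both hemispheric networks (weights + binary stack) of one subject."""
    dens = subject_densities(vertex_table, parcellation, density_config)
    return {
        h: build_network(subject_id or vertex_table.attrs.get("subject_id", ""),
                         h, dens[h], grid)
        for h in ("L", "R")
    }


def _network_metric_rows(
    net: HemisphericNetwork,
    randomization: RandomizationConfig | None,
    rand_seed: int | None = None,
):
    """(global rows, local DataFrame) for one hemispheric network."""
    grows = []
    ks, subs, degs, enods = [], [], [], []
    labels = np.asarray(net.labels)
    for k, a in net.binaries.items():
        rc = None
        if randomization is not None:
            rc = dataclasses.replace(
                randomization,
                seed=rand_seed if rand_seed is not None else randomization.seed,
            )
        gm = compute_global_metrics(a, randomization=rc)
        base = {"subject_id": net.subject_id, "hemisphere": net.hemisphere,
                "sparsity": k}
        vals = {"Lp": gm.lp, "Cp": gm.cp, "E_global": gm.e_global,
                "E_local": gm.e_local}
        if gm.sigma is not None:
            vals.update({"Lp_norm": gm.lam, "Cp_norm": gm.gamma,
                         "sigma": gm.sigma})
        for m, v in vals.items():
            grows.append({**base, "metric": m, "value": v})
        ks.append(np.full(len(labels), k))
        subs.append(labels)
        degs.append(degree_centrality(a).astype(float))
        enods.append(nodal_efficiency(all_pairs_distances(a, validate=False)))
    k_arr = np.concatenate(ks)
    s_arr = np.concatenate(subs)
    ldf = pd.DataFrame({
        "subject_id": net.subject_id,
        "hemisphere": net.hemisphere,
        "sparsity": np.tile(k_arr, 2),
        "subregion_id": np.tile(s_arr, 2),
        "metric": np.repeat(np.array(["degree", "E_nodal"], dtype=object),
                            len(k_arr)),
        "value": np.concatenate([np.concatenate(degs),
                                 np.concatenate(enods)]),
    })
    return grows, ldf


def cohort_analysis(
    tables: list[pd.DataFrame],
    manifest: pd.DataFrame,
    parcellation: Parcellation,
    config: PipelineConfig,
) -> dict[str, pd.DataFrame]:
    """Run densities -> networks -> metrics -> integration -> AI in memory.

    Returns {'metrics_global', 'metrics_local', 'integrated_global',
    'integrated_local', 'ai'} as tidy DataFrames.
    """
    grows, lframes = [], []
    by_id = {t.attrs.get("subject_id", f"S{i:03d}"): t
             for i, t in enumerate(tables)}
    for sid in manifest["subject_id"]:
        table = by_id[sid]
        nets = subject_networks(table, parcellation, config.density,
                                config.sparsity, subject_id=sid)
        for h in ("L", "R"):
            seed = derive_seed(config.seed, f"rewire:{sid}:{h}")
            g, ldf = _network_metric_rows(nets[h], config.randomization, seed)
            grows += g
            lframes.append(ldf)
    mg = pd.DataFrame(grows)
    ml = pd.concat(lframes, ignore_index=True)
    ig = _integrate_global_table(mg, config.sparsity)
    il = _integrate_local_table(ml, parcellation, config.sparsity)
    ai = ai_table(ig, il)
    return {"metrics_global": mg, "metrics_local": ml,
            "integrated_global": ig, "integrated_local": il, "ai": ai}


def _integrate_global_table(mg: pd.DataFrame, grid: SparsityGrid) -> pd.DataFrame:
    rows = []
    for (sid, h, metric), sub in mg.groupby(["subject_id", "hemisphere",
                                             "metric"], sort=True):
        series = dict(zip(sub["sparsity"].astype(float), sub["value"]))
        rows.append({"subject_id": sid, "hemisphere": h, "metric": metric,
                     "value": integrate_global(series, grid)})
    return pd.DataFrame(rows)


def _integrate_local_table(
    ml: pd.DataFrame, parcellation: Parcellation, grid: SparsityGrid
) -> pd.DataFrame:
    rows = []
    for (sid, metric), sub in ml.groupby(["subject_id", "metric"], sort=True):
        integ = integrate_local(
            sub.rename(columns={"value": "value"}), parcellation, grid
        )
        for (h, region), v in integ.items():
            rows.append({"subject_id": sid, "hemisphere": h, "region": region,
                         "metric": metric, "value": v})
    return pd.DataFrame(rows)


def small_world_summary(
    tables: list[pd.DataFrame],
    manifest: pd.DataFrame,
    parcellation: Parcellation,
    config: PipelineConfig,
    random_efficiencies: bool = True,
) -> pd.DataFrame:
    """Per (subject, hemisphere, sparsity) small-world profile of the cohort.

    Columns: sigma, gamma, lam, e_global, e_local and — when
    ``random_efficiencies`` — e_global_ran / e_local_ran, the mean
    efficiencies of the degree-preserving surrogates (the "matched random
    network" curves).  Group-averaging sigma over subjects and hemispheres
    and scanning the sparsity grid reproduces the small-worldness profile.
    """
    from .metrics import (characteristic_path_length, clustering_coefficient,
                          global_efficiency, local_efficiency, rewire_random)
    if config.randomization is None:
        raise ValueError("small_world_summary needs a randomization config")
    by_id = {t.attrs.get("subject_id", f"S{i:03d}"): t
             for i, t in enumerate(tables)}
    rows = []
    for sid in manifest["subject_id"]:
        nets = subject_networks(by_id[sid], parcellation, config.density,
                                config.sparsity, subject_id=sid)
        for h in ("L", "R"):
            rc = dataclasses.replace(
                config.randomization,
                seed=derive_seed(config.seed, f"rewire:{sid}:{h}"))
            for k, a in nets[h].binaries.items():
                dist = all_pairs_distances(a, validate=False)
                lp = characteristic_path_length(dist)
                cp = clustering_coefficient(a)
                eg = global_efficiency(dist)
                el = local_efficiency(a)
                randoms = rewire_random(a, rc)
                rdists = [all_pairs_distances(r, validate=False)
                          for r in randoms]
                l_ran = float(np.mean([characteristic_path_length(d)
                                       for d in rdists]))
                c_ran = float(np.mean([clustering_coefficient(r)
                                       for r in randoms]))
                lam = lp / l_ran
                gamma = cp / c_ran
                row = {"subject_id": sid, "hemisphere": h, "sparsity": k,
                       "sigma": gamma / lam, "gamma": gamma, "lam": lam,
                       "e_global": eg, "e_local": el}
                if random_efficiencies:
                    row["e_global_ran"] = float(
                        np.mean([global_efficiency(d) for d in rdists]))
                    row["e_local_ran"] = float(
                        np.mean([local_efficiency(r) for r in randoms]))
                rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# statistics tables
# ---------------------------------------------------------------------------

def statistics_tables(
    manifest: pd.DataFrame,
    integrated_global: pd.DataFrame,
    ai: pd.DataFrame,
    integrated_local: pd.DataFrame | None,
    config: PipelineConfig,
) -> dict[str, pd.DataFrame]:
    """Table-1-style t-test tables plus rm-ANOVA tables, global and regional.

    Global metric tests are reported at uncorrected p; regional families (the
    homologous pairs, separately per metric and per test type) carry
    Benjamini-Hochberg adjusted p-values.
    """
    from .stats import fdr_bh, one_sample_t, rm_anova, two_sample_t

    meta = manifest.set_index("subject_id")[["gender", "age"]]
    names = global_metric_names(config)

    # --- global: rm-ANOVA ---
    anova_rows = []
    piv = integrated_global.pivot_table(index=["subject_id", "metric"],
                                        columns="hemisphere", values="value")
    for metric in names:
        sub = piv.xs(metric, level="metric")
        data = pd.DataFrame({
            "subject_id": sub.index,
            "left": sub["L"].to_numpy(),
            "right": sub["R"].to_numpy(),
            "gender": meta.loc[sub.index, "gender"].to_numpy(),
            "age": meta.loc[sub.index, "age"].to_numpy(),
        })
        r = rm_anova(data)
        anova_rows.append({"metric": metric, "f_gender": r.f_gender,
                           "p_gender": r.p_gender,
                           "f_hemisphere": r.f_hemisphere,
                           "p_hemisphere": r.p_hemisphere,
                           "f_interaction": r.f_interaction,
                           "p_interaction": r.p_interaction,
                           "df1": r.df1, "df2": r.df2})

    # --- global: AI t-tests, Table-1 layout ---
    gai = ai[ai["scope"] == "global"].merge(
        manifest[["subject_id", "gender"]], on="subject_id")
    trows = []
    for metric in names:
        sub = gai[gai["metric"] == metric]
        f = sub.loc[sub["gender"] == "F", "ai"].to_numpy()
        m = sub.loc[sub["gender"] == "M", "ai"].to_numpy()
        for grp, vals in (("F", f), ("M", m)):
            r = one_sample_t(vals, metric=metric, group=grp)
            trows.append({"test": f"within_{'female' if grp == 'F' else 'male'}",
                          "metric": metric, "t": r.t, "df": r.df, "p": r.p,
                          "mean_ai": r.mean_ai})
        r = two_sample_t(f, m, metric=metric, welch=config.welch)
        trows.append({"test": "between_groups", "metric": metric, "t": r.t,
                      "df": r.df, "p": r.p, "mean_ai": r.mean_ai})

    out = {
        "global_anova": pd.DataFrame(anova_rows),
        "global_ttests": pd.DataFrame(trows),
    }

    # --- regional families with FDR ---
    if integrated_local is not None and not ai[ai["scope"] == "region"].empty:
        rai = ai[ai["scope"] == "region"].merge(
            manifest[["subject_id", "gender", "age"]], on="subject_id")
        pivl = integrated_local.pivot_table(
            index=["subject_id", "metric", "region"], columns="hemisphere",
            values="value")
        lrows, arows = [], []
        for metric in sorted(rai["metric"].unique()):
            msub = rai[rai["metric"] == metric]
            regions = sorted(msub["region"].unique())
            fam: dict[str, list] = {"within_female": [], "within_male": [],
                                    "between_groups": []}
            a_effects: dict[str, list] = {"gender": [], "hemisphere": [],
                                          "interaction": []}
            for region in regions:
                rsub = msub[msub["region"] == region]
                f = rsub.loc[rsub["gender"] == "F", "ai"].to_numpy()
                m = rsub.loc[rsub["gender"] == "M", "ai"].to_numpy()
                rf = one_sample_t(f, metric=metric, region=region, group="F",
                                  scope="region")
                rm = one_sample_t(m, metric=metric, region=region, group="M",
                                  scope="region")
                rb = two_sample_t(f, m, metric=metric, region=region,
                                  scope="region", welch=config.welch)
                fam["within_female"].append((region, rf))
                fam["within_male"].append((region, rm))
                fam["between_groups"].append((region, rb))

                lr = pivl.xs((metric, region), level=("metric", "region"))
                data = pd.DataFrame({
                    "subject_id": lr.index,
                    "left": lr["L"].to_numpy(),
                    "right": lr["R"].to_numpy(),
                    "gender": meta.loc[lr.index, "gender"].to_numpy(),
                    "age": meta.loc[lr.index, "age"].to_numpy(),
                })
                ar = rm_anova(data)
                a_effects["gender"].append((region, ar.f_gender, ar.p_gender))
                a_effects["hemisphere"].append(
                    (region, ar.f_hemisphere, ar.p_hemisphere))
                a_effects["interaction"].append(
                    (region, ar.f_interaction, ar.p_interaction))

            for test, results in fam.items():
                adj = fdr_bh([r.p for _, r in results], q=config.fdr_q)
                for (region, r), (_, row) in zip(results, adj.iterrows()):
                    lrows.append({"test": test, "metric": metric,
                                  "region": region, "t": r.t, "df": r.df,
                                  "p": r.p, "p_fdr": row["p_adjusted"],
                                  "rejected": bool(row["rejected"]),
                                  "mean_ai": r.mean_ai})
            for effect, results in a_effects.items():
                adj = fdr_bh([p for _, _, p in results], q=config.fdr_q)
                for (region, fv, pv), (_, row) in zip(results, adj.iterrows()):
                    arows.append({"effect": effect, "metric": metric,
                                  "region": region, "f": fv, "p": pv,
                                  "p_fdr": row["p_adjusted"],
                                  "rejected": bool(row["rejected"])})
        out["local_ttests"] = pd.DataFrame(lrows)
        out["local_anova"] = pd.DataFrame(arows)
    return out


# ---------------------------------------------------------------------------
# on-disk staged pipeline
# ---------------------------------------------------------------------------

def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False)


def _marker_path(run_dir: Path, stage: str) -> Path:
    return run_dir / f"{stage}.done.json"


def _stage_hash(config: PipelineConfig, run_dir: Path, stage: str) -> str:
    parts = [config.config_hash()]
    idx = STAGES.index(stage)
    for up in STAGES[:idx]:
        marker = _marker_path(run_dir, up)
        if marker.exists():
            parts.append(json.loads(marker.read_text())["hash"])
    return hashlib.sha256("|".join(parts).encode()).hexdigest()[:16]


def _stage_done(config: PipelineConfig, run_dir: Path, stage: str) -> bool:
    marker = _marker_path(run_dir, stage)
    if not marker.exists():
        return False
    return json.loads(marker.read_text())["hash"] == _stage_hash(config, run_dir, stage)


def _mark_done(config: PipelineConfig, run_dir: Path, stage: str) -> None:
    _marker_path(run_dir, stage).write_text(
        json.dumps({"stage": stage,
                    "hash": _stage_hash(config, run_dir, stage)}))


def _load_cohort(run_dir: Path):
    manifest = data_io.read_manifest(run_dir / "cohort" / "manifest_filtered.csv")
    tables = []
    for sid in manifest["subject_id"]:
        t = data_io.read_vertex_table(run_dir / "cohort" / f"sub-{sid}.tsv")
        t.attrs["subject_id"] = sid
        tables.append(t)
    return tables, manifest


def _load_parcellation(run_dir: Path) -> Parcellation:
    vs = pd.read_csv(run_dir / "parcellation" / "vertex_subregion.tsv", sep="\t")
    subs = pd.read_csv(run_dir / "parcellation" / "subregions.tsv", sep="\t")
    return Parcellation(
        vertex_subregion=vs.set_index("vertex_id")["subregion_id"],
        subregions=subs,
    )


def run_stage(config: PipelineConfig, run_dir: str | Path, stage: str) -> None:
    """Execute one pipeline stage (idempotent; requires upstream stages)."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    config.validate()
    idx = STAGES.index(stage)
    for up in STAGES[:idx]:
        if not _stage_done(config, run_dir, up):
            raise RuntimeError(f"stage {stage!r} requires completed stage {up!r}")
    if _stage_done(config, run_dir, stage):
        logger.info("stage %s already complete; skipping", stage)
        return
    logger.info("running stage %s", stage)
    try:
        _STAGE_FNS[stage](config, run_dir)
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    _mark_done(config, run_dir, stage)


def run_all(config: PipelineConfig, run_dir: str | Path) -> Path:
    """Run every stage in order; returns the run directory."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    from . import __version__
    manifest = json.dumps({
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
    }, indent=2, default=str)
    manifest_path = run_dir / "run_manifest.json"
    if not manifest_path.exists() or manifest_path.read_text() != manifest:
        manifest_path.write_text(manifest)
    for stage in STAGES:
        run_stage(config, run_dir, stage)
    return run_dir


# -- individual stage bodies -------------------------------------------------

def _do_generate(config: PipelineConfig, run_dir: Path) -> None:
    gen = dataclasses.replace(config.generator,
                              seed=derive_seed(config.seed, "generate"))
    template = generate_surface(gen)
    tables, manifest = generate_cohort(template, gen)
    cohort_dir = run_dir / "cohort"
    cohort_dir.mkdir(exist_ok=True)
    data_io.write_manifest(manifest, cohort_dir / "manifest.csv")
    kept = data_io.filter_cohort(manifest, gen.handedness_min)
    data_io.write_manifest(kept, cohort_dir / "manifest_filtered.csv")
    for table in tables:
        sid = table.attrs["subject_id"]
        if sid in set(kept["subject_id"]):
            data_io.write_vertex_table(table, cohort_dir / f"sub-{sid}.tsv")


def _do_parcellate(config: PipelineConfig, run_dir: Path) -> None:
    tables, _ = _load_cohort(run_dir)
    template = tables[0].drop(columns=["thickness"])
    parc = upsample(template, seed=derive_seed(config.seed, "parcellate"),
                    target_per_hemisphere=config.target_per_hemisphere,
                    size_floor=config.size_floor)
    pdir = run_dir / "parcellation"
    pdir.mkdir(exist_ok=True)
    parc.vertex_subregion.rename("subregion_id").reset_index().to_csv(
        pdir / "vertex_subregion.tsv", sep="\t", index=False)
    parc.subregions.to_csv(pdir / "subregions.tsv", sep="\t", index=False)


def _do_densities(config: PipelineConfig, run_dir: Path) -> None:
    tables, manifest = _load_cohort(run_dir)
    parc = _load_parcellation(run_dir)
    ddir = run_dir / "densities"
    ddir.mkdir(exist_ok=True)
    for table in tables:
        sid = table.attrs["subject_id"]
        dens = subject_densities(table, parc, config.density)
        rows = []
        for h in ("L", "R"):
            for d in dens[h]:
                rows.append({"subregion_id": d.subregion_id, "hemisphere": h,
                             **{f"m{i}": v for i, v in enumerate(d.mass)}})
        df = pd.DataFrame(rows)
        grid = dens["L"][0].grid
        with open(ddir / f"sub-{sid}.csv", "w") as fh:
            fh.write("# grid=" + ",".join(repr(float(g)) for g in grid) + "\n")
            df.to_csv(fh, index=False, float_format=data_io.FLOAT_FMT)


def _read_densities(path: Path):
    from .density import RegionDensity
    with open(path) as fh:
        header = fh.readline()
        grid = np.array([float(v) for v in header.strip()[len("# grid="):].split(",")])
        df = pd.read_csv(fh)
    mcols = [c for c in df.columns if c.startswith("m")]
    out = {"L": [], "R": []}
    for _, row in df.iterrows():
        mass = row[mcols].to_numpy(dtype=float)
        out[row["hemisphere"]].append(
            RegionDensity(int(row["subregion_id"]), grid, mass / mass.sum()))
    return out


def _do_networks(config: PipelineConfig, run_dir: Path) -> None:
    _, manifest = _load_cohort(run_dir)
    ndir = run_dir / "networks"
    ndir.mkdir(exist_ok=True)
    for sid in manifest["subject_id"]:
        dens = _read_densities(run_dir / "densities" / f"sub-{sid}.csv")
        for h in ("L", "R"):
            net = build_network(sid, h, dens[h], config.sparsity)
            data_io.write_matrix(
                data_io.MatrixArtifact(sid, h, "weights", net.labels,
                                       net.weights),
                ndir / f"sub-{sid}_hemi-{h}_weights.tsv")


def _do_metrics(config: PipelineConfig, run_dir: Path) -> None:
    _, manifest = _load_cohort(run_dir)
    mdir = run_dir / "metrics"
    mdir.mkdir(exist_ok=True)
    grows, lframes = [], []
    for sid in manifest["subject_id"]:
        for h in ("L", "R"):
            art = data_io.read_matrix(
                run_dir / "networks" / f"sub-{sid}_hemi-{h}_weights.tsv")
            net = HemisphericNetwork(
                subject_id=sid, hemisphere=h, labels=art.labels,
                weights=art.values,
                binaries=binarize(art.values, config.sparsity))
            seed = derive_seed(config.seed, f"rewire:{sid}:{h}")
            g, ldf = _network_metric_rows(net, config.randomization, seed)
            grows += g
            lframes.append(ldf)
    _write_csv(pd.DataFrame(grows), mdir / "global.csv")
    _write_csv(pd.concat(lframes, ignore_index=True), mdir / "local.csv")


def _do_integrate(config: PipelineConfig, run_dir: Path) -> None:
    parc = _load_parcellation(run_dir)
    mg = pd.read_csv(run_dir / "metrics" / "global.csv")
    ml = pd.read_csv(run_dir / "metrics" / "local.csv")
    idir = run_dir / "integrated"
    idir.mkdir(exist_ok=True)
    _write_csv(_integrate_global_table(mg, config.sparsity),
               idir / "global.csv")
    _write_csv(_integrate_local_table(ml, parc, config.sparsity),
               idir / "local.csv")


def _do_asymmetry(config: PipelineConfig, run_dir: Path) -> None:
    ig = pd.read_csv(run_dir / "integrated" / "global.csv")
    il = pd.read_csv(run_dir / "integrated" / "local.csv")
    _write_csv(ai_table(ig, il), run_dir / "ai.csv")


def _do_stats(config: PipelineConfig, run_dir: Path) -> None:
    _, manifest = _load_cohort(run_dir)
    ig = pd.read_csv(run_dir / "integrated" / "global.csv")
    il = pd.read_csv(run_dir / "integrated" / "local.csv")
    ai = pd.read_csv(run_dir / "ai.csv", keep_default_na=False,
                     dtype={"region": str})
    ai["ai"] = ai["ai"].astype(float)
    sdir = run_dir / "stats"
    sdir.mkdir(exist_ok=True)
    tables = statistics_tables(manifest, ig, ai, il, config)
    for name, df in tables.items():
        _write_csv(df, sdir / f"{name}.csv")


_STAGE_FNS = {
    "generate": _do_generate,
    "parcellate": _do_parcellate,
    "densities": _do_densities,
    "networks": _do_networks,
    "metrics": _do_metrics,
    "integrate": _do_integrate,
    "asymmetry": _do_asymmetry,
    "stats": _do_stats,
}
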