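"""Config-driven orchestration of the heat-stress, survey and stats stages.

A run config (YAML or dict) lists sites, each with a climatology (MMM),
either a logger CSV or a synthetic climate scenario, and survey inputs
(point-score CSVs / roving CSVs, or generator blocks). Each stage writes
plain CSV/TSV outputs plus a JSON manifest recording config values, the
seed, and a SHA-256 per output file.
"""

from __future__ import annotations

import hashlib
import json
import logging
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import scoring, stats, synth, thermal

log = logging.getLogger("reefstress")

DEFAULT_OPTIONS = {
    "rule": "all_positive",
    "window_days": 84,
    "n_perm": 9999,
    "chi2_correction": "none",
    "cover_basis": "hard_coral_points",
    "min_coverage": 0.75,
}


class ConfigError(ValueError):
    pass


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "sites" not in cfg:
        raise ConfigError(f"{path}: config must be a mapping with a 'sites' list")
    return cfg


def _options(cfg: dict, **overrides) -> dict:
    opts = {**DEFAULT_OPTIONS, **cfg.get("options", {})}
    opts.update({k: v for k, v in overrides.items() if v is not None})
    return opts


def _seed(cfg: dict, override=None) -> int:
    seed = override if override is not None else cfg.get("seed")
    if seed is None:
        raise ConfigError("a seed is required when any stochastic stage runs")
    return int(seed)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(out_dir: Path, stage: str, cfg: dict, seed, outputs: list[Path]):
    manifest = {
        "stage": stage,
        "seed": seed,
        "options": _options(cfg),
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    path = out_dir / f"manifest_{stage}.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    log.info("stage %s: wrote %d outputs to %s", stage, len(outputs), out_dir)
    return path


def _scenario_from_cfg(site: dict, seed: int) -> tuple[synth.ClimateScenario, date, date]:
    sc = dict(site["scenario"])
    start = pd.Timestamp(sc.pop("start")).date()
    end = pd.Timestamp(sc.pop("end")).date()
    hw = sc.pop("heatwave", None)
    heatwave = None
    if hw:
        heatwave = synth.Heatwave(
            start=pd.Timestamp(hw["start"]).date(),
            duration_days=int(hw["duration_days"]),
            magnitude=float(hw["magnitude"]),
            ramp_days=int(hw.get("ramp_days", 0)),
        )
    scenario = synth.ClimateScenario(
        site_id=site["site_id"],
        mmm=float(site["mmm"]),
        habitat=site.get("habitat", "unspecified"),
        heatwave=heatwave,
        seed=seed,
        **sc,
    )
    return scenario, start, end


def _temperature_series(site: dict, seed: int) -> thermal.TemperatureSeries:
    if "logger_csv" in site:
        path = Path(site["logger_csv"])
        if not path.exists():
            raise ConfigError(f"site {site['site_id']}: missing logger file {path}")
        return thermal.TemperatureSeries.from_csv(
            path, site_id=site["site_id"], habitat=site.get("habitat", "unspecified")
        )
    if "scenario" in site:
        scenario, start, end = _scenario_from_cfg(site, seed)
        return synth.gen_temperature(scenario, start, end)
    raise ConfigError(f"site {site['site_id']}: needs logger_csv or scenario")


def run_heat_stress(cfg: dict, out_dir, seed=None, **option_overrides) -> pd.DataFrame:
    """Per-site heat-stress profiles plus a both-rules summary table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    opts = _options(cfg, **option_overrides)
    seed = _seed(cfg, seed)
    outputs = []
    rows = []
    for i, site in enumerate(cfg["sites"]):
        if "logger_csv" not in site and "scenario" not in site:
            continue
        series = _temperature_series(site, seed + i)
        clim = thermal.Climatology(
            site_id=site["site_id"], mmm=float(site["mmm"]),
            source=site.get("mmm_source", "config"),
        )
        profiles = {}
        for rule in thermal.ACCUMULATION_RULES:
            profiles[rule] = thermal.heat_stress_profile(
                series,
                clim,
                rule=rule,
                window_days=int(opts["window_days"]),
                min_coverage=float(opts["min_coverage"]),
            )
        main = profiles[opts["rule"]]
        path = out_dir / f"heat_{site['site_id']}.csv"
        main.to_csv(path)
        outputs.append(path)
        summ = thermal.exceedance_summary(main)
        s_all = thermal.exceedance_summary(profiles["all_positive"])
        s_noaa = thermal.exceedance_summary(profiles["noaa_ge1"])
        rows.append(
            {
                "site": site["site_id"],
                "habitat": site.get("habitat", "unspecified"),
                "mmm": float(site["mmm"]),
                "days_above_mmm": summ.days_above_mmm,
                "days_above_threshold": summ.days_above_threshold,
                "max_anomaly_c": round(summ.max_anomaly_c, 2),
                "dhd_all_positive": round(s_all.final_dhd, 1),
                "dhw_all_positive": s_all.final_dhw_reported,
                "dhd_noaa_ge1": round(s_noaa.final_dhd, 1),
                "dhw_noaa_ge1": s_noaa.final_dhw_reported,
                "n_gap_days": summ.n_gap_days,
            }
        )
    summary = pd.DataFrame(rows)
    spath = out_dir / "heat_summary.csv"
    summary.to_csv(spath, index=False)
    outputs.append(spath)
    write_manifest(out_dir, "heat", cfg, seed, outputs)
    return summary


def _survey_points(site: dict, survey: dict, seed: int) -> pd.DataFrame:
    if "points_csv" in survey:
        path = Path(survey["points_csv"])
        if not path.exists():
            raise ConfigError(
                f"site {site['site_id']}: missing survey file {path}"
            )
        df = pd.read_csv(path, keep_default_na=False)
        missing = set(scoring.POINT_COLUMNS[:2]) - set(df.columns)
        if missing:
            raise ConfigError(
                f"{path}: missing columns {sorted(missing)} (header row 1)"
            )
        return df
    if "generate" in survey:
        gen = dict(survey["generate"])
        profile = synth.CommunityProfile(
            site_id=site["site_id"], **gen.pop("profile", {})
        )
        response = synth.BleachingResponse(**gen.pop("response", {}))
        return synth.gen_survey(
            profile,
            response,
            dhw_at_survey=float(gen.pop("dhw")),
            seed=seed,
            habitat=site.get("habitat", "unspecified"),
            site=site["site_id"],
            survey_date=str(survey.get("time", "")),
            **gen,
        )[1]
    raise ConfigError(
        f"site {site['site_id']}: survey entry needs points_csv or generate"
    )


def _roving_frame(site: dict, rov: dict, seed: int) -> pd.DataFrame:
    if "csv" in rov:
        path = Path(rov["csv"])
        if not path.exists():
            raise ConfigError(f"site {site['site_id']}: missing roving file {path}")
        return pd.read_csv(path)
    if "generate" in rov:
        gen = dict(rov["generate"])
        response = synth.BleachingResponse(**gen.pop("response", {}))
        return synth.gen_roving(
            genus=gen.pop("genus", "Turbinaria"),
            response=response,
            dhw=float(gen.pop("dhw", 0.0)),
            seed=seed,
            site=site["site_id"],
            survey_date=str(rov.get("time", "")),
            **gen,
        )
    raise ConfigError(f"site {site['site_id']}: roving entry needs csv or generate")


def collect_surveys(cfg: dict, seed: int) -> pd.DataFrame:
    """All point-score tables concatenated, tagged with site and time."""
    frames = []
    for i, site in enumerate(cfg["sites"]):
        for j, survey in enumerate(site.get("surveys", [])):
            df = _survey_points(site, survey, seed + 1000 * i + j)
            df = df.copy()
            df["site"] = site["site_id"]
            df["time"] = str(survey.get("time", j + 1))
            frames.append(df)
    if not frames:
        raise ConfigError("no survey inputs in config")
    return pd.concat(frames, ignore_index=True)


def run_survey_analysis(
    cfg: dict, out_dir, seed=None, **option_overrides
) -> dict[str, pd.DataFrame]:
    """Site x time health/abundance summaries (mean +/- SE over transects)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    opts = _options(cfg, **option_overrides)
    seed = _seed(cfg, seed)
    points = collect_surveys(cfg, seed)
    outputs = []

    ppath = out_dir / "survey_points.csv"
    points.to_csv(ppath, index=False)
    outputs.append(ppath)

    # per-quadrat health percentages on the configured cover basis
    basis = opts["cover_basis"]
    health_pct = _quadrat_health_percent(points, basis)
    summary = scoring.transect_summary(
        health_pct, group_cols=("site", "time")
    ).reset_index()
    hpath = out_dir / "survey_health_summary.tsv"
    summary.to_csv(hpath, sep="\t", index=False)
    outputs.append(hpath)

    # dominant genus per site x time (share of hard-coral points)
    coral = points[points["category"] == "hard_coral"]
    dom = (
        coral.groupby(["site", "time", "genus"]).size().rename("n_points")
        .reset_index()
        .sort_values(["site", "time", "n_points"], ascending=[True, True, False])
        .groupby(["site", "time"])
        .head(1)
    )
    dom["pct_of_coral"] = [
        round(
            100.0
            * n
            / len(coral[(coral["site"] == s) & (coral["time"] == t)]),
            1,
        )
        for s, t, n in zip(dom["site"], dom["time"], dom["n_points"])
    ]
    dpath = out_dir / "survey_dominant_genus.tsv"
    dom.to_csv(dpath, sep="\t", index=False)
    outputs.append(dpath)

    # roving tallies
    rov_rows = []
    for i, site in enumerate(cfg["sites"]):
        for j, rov in enumerate(site.get("roving", [])):
            df = _roving_frame(site, rov, seed + 5000 * i + j)
            tally = scoring.roving_tally(
                df, survey_id=f"{site['site_id']}:{rov.get('time', j + 1)}"
            )
            pct = tally.percentages()
            rov_rows.append(
                {
                    "site": site["site_id"],
                    "time": str(rov.get("time", j + 1)),
                    "n_colonies": tally.n_colonies,
                    **{f"n_{c}": tally.counts.get(c, 0) for c in scoring.HEALTH_CODES},
                    **{f"pct_{c}": round(pct[c], 1) for c in scoring.HEALTH_CODES},
                }
            )
    result = {"health_summary": summary, "dominant_genus": dom}
    if rov_rows:
        rov_df = pd.DataFrame(rov_rows)
        rpath = out_dir / "roving_summary.tsv"
        rov_df.to_csv(rpath, sep="\t", index=False)
        outputs.append(rpath)
        result["roving"] = rov_df
    write_manifest(out_dir, "survey", cfg, seed, outputs)
    return result


def _quadrat_health_percent(points: pd.DataFrame, basis: str) -> pd.DataFrame:
    """Per-quadrat health-category percentages for the summary stage."""
    rows = []
    keys = ["site", "time", "transect_id", "quadrat_id"]
    for (site, time, tid, qid), sub in points.groupby(keys, sort=True):
        coral = sub[sub["category"] == "hard_coral"]
        denom = len(sub) if basis == "all_points" else len(coral)
        if denom == 0:
            continue
        counts = coral.groupby("health").size()
        rows.append(
            {
                "site": site,
                "time": time,
                "transect_id": tid,
                "quadrat_id": qid,
                **{
                    c: 100.0 * counts.get(c, 0) / denom
                    for c in scoring.HEALTH_CODES
                },
            }
        )
    if not rows:
        raise ConfigError("no quadrat with a usable denominator")
    return pd.DataFrame(rows).drop(columns=["quadrat_id"])


def run_stats(cfg: dict, out_dir, seed=None, **option_overrides) -> pd.DataFrame:
    """PERMANOVAs, pairwise tests, PCA and chi-square over the survey data.

    Emits a Table-2-style TSV (term, df, F, p, adjusted p) stamped with
    seed and permutation count; exit behaviour reflects completion only,
    never significance.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    opts = _options(cfg, **option_overrides)
    seed = _seed(cfg, seed)
    n_perm = int(opts["n_perm"])
    points = collect_surveys(cfg, seed)
    outputs = []
    rows = []

    wide = scoring.abundance_from_points(
        points, grouping="genus_health", meta_cols=("site", "time")
    )
    meta = wide[["site", "time", "transect_id"]]
    classes = wide.drop(columns=["site", "time", "transect_id"])
    m = stats.AbundanceMatrix(data=classes, meta=meta)
    msq = stats.sqrt_transform(m)
    apath = out_dir / "abundance_matrix.csv"
    wide.to_csv(apath, index=False)
    outputs.append(apath)

    rng = np.random.SeedSequence(seed)
    seeds = iter(rng.spawn(8))

    times = sorted(meta["time"].unique())
    sites_per_time = meta.groupby("time")["site"].nunique()

    # two-way time x site on sites present at every time point
    if len(times) >= 2:
        full_sites = [
            s
            for s, grp in meta.groupby("site")["time"]
            if set(grp) == set(times)
        ]
        sel = meta["site"].isin(full_sites).to_numpy()
        if sel.sum() >= 8 and len(full_sites) >= 2:
            sub = stats.AbundanceMatrix(
                data=msq.data.loc[sel].reset_index(drop=True),
                meta=meta.loc[sel].reset_index(drop=True),
                transform_state="sqrt",
            )
            d = stats.bray_curtis(sub)
            res = stats.permanova_twoway(
                d,
                sub.meta["time"],
                sub.meta["site"],
                n_perm=n_perm,
                seed=np.random.default_rng(next(seeds)),
                names=("Time", "Site"),
            )
            for t in res.terms:
                rows.append(
                    _stat_row("two-way PERMANOVA (time x site)", t.name, t.df, t.f, t.p)
                )
            rows.append(
                _stat_row(
                    "two-way PERMANOVA (time x site)", "Residual", res.residual_df,
                    None, None,
                )
            )

    # one-way site effect at the final time point, with pairwise post-hoc
    t_last = times[-1]
    sel = (meta["time"] == t_last).to_numpy()
    if sel.sum() >= 4 and sites_per_time[t_last] >= 2:
        sub = stats.AbundanceMatrix(
            data=msq.data.loc[sel].reset_index(drop=True),
            meta=meta.loc[sel].reset_index(drop=True),
            transform_state="sqrt",
        )
        d = stats.bray_curtis(sub)
        res = stats.permanova_oneway(
            sub_d := d,
            sub.meta["site"],
            n_perm=n_perm,
            seed=np.random.default_rng(next(seeds)),
            factor_name="Site",
        )
        t = res.terms[0]
        rows.append(
            _stat_row(f"one-way PERMANOVA (site at time {t_last})", t.name, t.df, t.f, t.p)
        )
        if sub.meta["site"].nunique() >= 3:
            pw = stats.pairwise_posthoc(
                sub_d, sub.meta["site"].to_numpy(), n_perm=n_perm,
                seed=int(np.random.default_rng(next(seeds)).integers(2**31)),
            )
            pw_path = out_dir / "pairwise_site.tsv"
            pw.to_csv(pw_path, sep="\t", index=False)
            outputs.append(pw_path)
            for _, r in pw.iterrows():
                rows.append(
                    _stat_row(
                        f"pairwise (site at time {t_last})",
                        f"{r['group1']} vs {r['group2']}",
                        int(r["df"]), r["F"], r["p_raw"], r["p_adjusted"],
                    )
                )

    # PCA ordination over all transects
    try:
        p = stats.pca(msq)
        sc = p.scores.copy()
        sc.insert(0, "transect_id", meta["transect_id"].to_numpy())
        sc.insert(0, "time", meta["time"].to_numpy())
        sc.insert(0, "site", meta["site"].to_numpy())
        spath = out_dir / "pca_scores.csv"
        sc.to_csv(spath, index=False)
        lpath = out_dir / "pca_loadings.csv"
        p.loadings.to_csv(lpath)
        outputs.extend([spath, lpath])
    except stats.InputError as exc:
        log.warning("PCA skipped: %s", exc)

    # chi-square between time points on pooled roving counts
    rov_counts: dict[str, dict[str, int]] = {}
    for i, site in enumerate(cfg["sites"]):
        for j, rov in enumerate(site.get("roving", [])):
            df = _roving_frame(site, rov, seed + 5000 * i + j)
            tally = scoring.roving_tally(df, survey_id=str(rov.get("time", j + 1)))
            tkey = str(rov.get("time", j + 1))
            agg = rov_counts.setdefault(tkey, {})
            for c, n in tally.counts.items():
                agg[c] = agg.get(c, 0) + n
    if len(rov_counts) >= 2:
        cols = [
            c
            for c in scoring.HEALTH_CODES
            if any(cnt.get(c, 0) > 0 for cnt in rov_counts.values())
        ]
        tbl = stats.ContingencyTable(
            counts=np.array(
                [[rov_counts[t].get(c, 0) for c in cols] for t in sorted(rov_counts)]
            ),
            row_labels=sorted(rov_counts),
            col_labels=cols,
        )
        chi = stats.chi_square(tbl, correction=opts["chi2_correction"])
        rows.append(
            _stat_row(
                "chi-square (roving, pooled, between times)", "Time",
                chi.df, chi.statistic, chi.p,
            )
        )

    table = pd.DataFrame(
        rows, columns=["analysis", "term", "df", "F_or_chi2", "p", "p_adjusted"]
    )
    table["seed"] = seed
    table["n_perm"] = n_perm
    tpath = out_dir / "stats_results.tsv"
    table.to_csv(tpath, sep="\t", index=False)
    outputs.append(tpath)
    write_manifest(out_dir, "stats", cfg, seed, outputs)
    return table


def _stat_row(analysis, term, df, stat, p, p_adj=None) -> dict:
    return {
        "analysis": analysis,
        "term": term,
        "df": df,
        "F_or_chi2": None if stat is None else round(float(stat), 4),
        "p": None if p is None else round(float(p), 6),
        "p_adjusted": None if p_adj is None else round(float(p_adj), 6),
    }


def demo_config(seed: int = 1, n_perm: int = 999) -> dict:
    """Five synthetic sites emulating the motivating regional design.

    Two heatwave-affected northern sites (one intertidal, one subtidal,
    differing only in tidal regime and tolerance shift), a satellite-only
    site surveyed once, a site with no heat stress, and a temperate site
    surveyed by roving divers.
    """
    hw = {"start": "2016-01-10", "duration_days": 80, "magnitude": 1.2, "ramp_days": 10}
    season = {
        "mean_annual": 29.0,
        "seasonal_amplitude": 1.8,
        "season_phase": 45,
        "noise_sd": 0.15,
        "start": "2015-11-01",
        "end": "2016-04-20",
    }
    surveys_hot = [
        {"time": "t1", "generate": {"dhw": 0.3, "n_transects": 6, "quadrats_per_transect": 4}},
        {"time": "t2", "generate": {"dhw": 4.5, "n_transects": 6, "quadrats_per_transect": 4}},
    ]
    surveys_cool = [
        {"time": "t1", "generate": {"dhw": 0.0, "n_transects": 6, "quadrats_per_transect": 4}},
        {"time": "t2", "generate": {"dhw": 0.0, "n_transects": 6, "quadrats_per_transect": 4}},
    ]
    return {
        "seed": seed,
        "options": {"n_perm": n_perm},
        "sites": [
            {
                "site_id": "north_reef",
                "habitat": "open",
                "mmm": 30.8,
                "scenario": {**season, "mean_annual": 30.2, "heatwave": hw},
                "surveys": [
                    {"time": "t2", "generate": {"dhw": 6.0, "n_transects": 4, "quadrats_per_transect": 4}},
                ],
            },
            {
                "site_id": "bay_intertidal",
                "habitat": "intertidal",
                "mmm": 30.8,
                "scenario": {**season, "mean_annual": 30.0, "tidal_amplitude": 3.0, "heatwave": hw},
                "surveys": surveys_hot,
            },
            {
                "site_id": "bay_subtidal",
                "habitat": "subtidal",
                "mmm": 30.8,
                "scenario": {**season, "mean_annual": 30.0, "tidal_amplitude": 0.5, "heatwave": hw},
                "surveys": surveys_hot,
            },
            {
                "site_id": "mid_reef",
                "habitat": "open",
                "mmm": 27.4,
                "scenario": {**season, "mean_annual": 25.8},
                "surveys": surveys_cool,
            },
            {
                "site_id": "south_bay",
                "habitat": "open",
                "mmm": 21.3,
                "scenario": {**season, "mean_annual": 19.5, "seasonal_amplitude": 2.0},
                "surveys": surveys_cool,
                "roving": [
                    {"time": "t1", "generate": {"n_colonies": 45, "dhw": 0.0}},
                    {"time": "t2", "generate": {"n_colonies": 78, "dhw": 0.0}},
                ],
            },
        ],
    }


def run_demo(out_dir, seed: int = 1, n_perm: int = 999) -> dict:
    """Chain simulate -> heat -> survey -> stats on the built-in scenario."""
    out_dir = Path(out_dir)
    cfg = demo_config(seed=seed, n_perm=n_perm)
    heat = run_heat_stress(cfg, out_dir / "heat", seed=seed)
    survey = run_survey_analysis(cfg, out_dir / "survey", seed=seed)
    table = run_stats(cfg, out_dir / "stats", seed=seed)
    return {"heat": heat, "survey": survey, "stats": table, "config": cfg}
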