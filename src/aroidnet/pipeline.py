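"""End-to-end analysis: input -> metrics -> null models -> JSON report.

``run_full_analysis`` computes, for one interaction web (and optionally
the per-stratum webs behind it), the full battery: network- and
species-level specialization, niche overlap, modularity with restarts,
HITS centrality, Patefield null ensembles, per-host IFA tables, the
guild x host G-test, and the diversity block (jackknife richness,
accumulation curve, beta-diversity decompositions across elevations).

A single global seed is expanded into independent per-stage seeds with
``numpy.random.SeedSequence`` under fixed stage keys, so adding a stage
never perturbs the draws of earlier ones.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import datasets, diversity, metrics, modularity, nulls
from .community import guild_abundance_table, ifa_table, williams_g_test
from .webs import (
    GuildMap,
    InteractionWeb,
    RecordTable,
    ValidationError,
    read_records,
    read_web,
)

__all__ = ["AnalysisConfig", "run_full_analysis", "stratify", "analyze_web"]

log = logging.getLogger("aroidnet")

_STAGE_KEYS = ("modularity", "null_h2", "null_q", "null_no", "accumulation")


def _stage_seeds(seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(len(_STAGE_KEYS))
    return {
        key: int(child.generate_state(1, dtype=np.uint32)[0]) % (2**31)
        for key, child in zip(_STAGE_KEYS, children)
    }


@dataclass(frozen=True)
class AnalysisConfig:
    """Inputs and settings of one full analysis run.

    Exactly one of ``fixture``, ``web_path`` or ``records_path`` selects
    the input; ``fixture="survey"`` analyses the reconstructed Los
    Tuxtlas web.
    """

    fixture: str | None = None
    web_path: str | None = None
    records_path: str | None = None
    seed: int = 0
    n_null: int = 100
    n_restarts: int = 20
    with_nulls: bool = True
    out_dir: str | None = None
    guilds: dict[str, str] | None = field(default=None)

    @classmethod
    def from_json(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def stratify(records: RecordTable, by: str = "elevation") -> dict[str, InteractionWeb]:
    """One trimmed web per stratum (elevation or host), keyed by stratum."""
    if by not in {"elevation", "host"}:
        raise ValidationError(f"unknown stratification field {by!r}")
    out: dict[str, InteractionWeb] = {}
    for key in sorted(records.frame[by].unique()):
        out[key] = records.subset(**{by: key}).to_web()
    return out


def _series_dict(s: pd.Series) -> dict[str, float]:
    return {str(k): float(v) for k, v in s.items()}


def analyze_web(
    web: InteractionWeb,
    seed: int = 0,
    n_null: int = 100,
    n_restarts: int = 20,
    with_nulls: bool = True,
) -> dict:
    """All single-web metrics as a JSON-serializable dictionary."""
    seeds = _stage_seeds(seed)
    spec = metrics.specialization(web)
    part = modularity.dirt_lpawb_plus(web, n_restarts=n_restarts, seed=seeds["modularity"])
    hits = metrics.hits_scores(web)
    no = metrics.mean_niche_overlap(web, "insects") if web.shape[0] >= 2 else None
    report: dict = {
        "shape": {"insects": web.shape[0], "hosts": web.shape[1], "individuals": web.m},
        "specialization": {
            "h2": spec.h2,
            "h2_min": spec.h2_min,
            "h2_max": spec.h2_max,
            "h2_prime": spec.h2_prime,
            "insect_dprime": _series_dict(spec.insect_dprime["d_prime"].dropna()),
            "host_dprime": _series_dict(spec.host_dprime["d_prime"].dropna()),
        },
        "niche_overlap_insects": no,
        "modularity": {
            "q": part.q,
            "n_modules": part.n_modules,
            "n_restarts": n_restarts,
            "seed": seeds["modularity"],
            "modules": part.as_dict(web),
        },
        "centrality": {
            "hub": _series_dict(hits.hub),
            "authority": _series_dict(hits.authority),
            "iterations": hits.n_iter,
        },
    }
    if with_nulls:
        ens_h2 = nulls.null_ensemble(web, "H2prime", n=n_null, seed=seeds["null_h2"], tail="greater")
        # a light restart schedule inside the null loop keeps 100 draws cheap
        ens_q = nulls.null_ensemble(
            web,
            nulls.make_statistic("Q", n_restarts=3, seed=seeds["null_q"]),
            n=n_null,
            seed=seeds["null_q"],
            tail="greater",
        )
        ens_no = (
            nulls.null_ensemble(web, "NO", n=n_null, seed=seeds["null_no"], tail="less")
            if no is not None
            else None
        )
        def _ens(e):
            return None if e is None else {
                "statistic": e.statistic,
                "observed": e.observed,
                "null_mean": e.null_mean,
                "null_sd": e.null_sd,
                "z": None if not e.z_defined else e.z,
                "p": e.p_value,
                "tail": e.tail,
                "n": e.n,
                "seed": e.seed,
                "significant": e.significant,
            }
        report["null_models"] = {
            "H2prime": _ens(ens_h2),
            "Q": _ens(ens_q),
            "NO": _ens(ens_no),
        }
    return report


def _checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_full_analysis(config: AnalysisConfig | str | Path) -> dict:
    """Run the configured analysis and return the report dictionary.

    When ``config.out_dir`` is set, writes ``report.json`` plus CSV side
    tables (d', centrality, module membership, IFA, accumulation curve).
    """
    if not isinstance(config, AnalysisConfig):
        config = AnalysisConfig.from_json(config)
    sources = [s for s in (config.fixture, config.web_path, config.records_path) if s]
    if len(sources) != 1:
        raise ValidationError("specify exactly one of fixture, web_path, records_path")

    records: RecordTable | None = None
    guilds: GuildMap | None = GuildMap(config.guilds) if config.guilds else None
    provenance: dict = {"seed": config.seed, "n_null": config.n_null, "n_restarts": config.n_restarts}
    if config.fixture:
        if config.fixture not in {"survey"}:
            raise ValidationError(f"unknown fixture {config.fixture!r}")
        web = datasets.survey_web()
        guilds = guilds or datasets.load_guilds()
        provenance["input"] = "fixture:survey"
    elif config.web_path:
        web = read_web(config.web_path).trim()
        provenance["input"] = str(config.web_path)
        provenance["sha256"] = _checksum(config.web_path)
    else:
        records = read_records(config.records_path)
        web = records.to_web()
        provenance["input"] = str(config.records_path)
        provenance["sha256"] = _checksum(config.records_path)

    log.info("input web: %d insects x %d hosts, m=%d", *web.shape, web.m)
    seeds = _stage_seeds(config.seed)
    report: dict = {"provenance": provenance}
    report["full_network"] = analyze_web(
        web, seed=config.seed, n_null=config.n_null,
        n_restarts=config.n_restarts, with_nulls=config.with_nulls,
    )

    if guilds is not None:
        table = guild_abundance_table(web, guilds)
        gres = williams_g_test(table.to_numpy())
        report["guilds"] = {
            "table": {g: _series_dict(row) for g, row in table.iterrows()},
            "g": gres.g,
            "q_williams": gres.q,
            "g_adj": gres.g_adj,
            "df": gres.df,
            "p": gres.p_value,
        }

    curve_out: pd.DataFrame | None = None
    if records is not None:
        strata = stratify(records, "elevation")
        report["per_elevation"] = {
            key: analyze_web(
                w, seed=config.seed, n_null=config.n_null,
                n_restarts=max(5, config.n_restarts // 2), with_nulls=False,
            )
            for key, w in strata.items()
            if min(w.shape) >= 2
        }
        report["ifa"] = {
            host: {
                sp: {"rf": float(row["rf"]), "ra": float(row["ra"]), "ifa": float(row["ifa"])}
                for sp, row in ifa_table(records, host).iterrows()
            }
            for host in records.hosts
        }
        jack = diversity.jackknife1(records)
        curve = diversity.accumulation_curve(records, n_perm=100, seed=seeds["accumulation"])
        div: dict = {
            "jackknife1": {
                "s_obs": jack.s_obs,
                "q1": jack.q1,
                "n_units": jack.n_units,
                "s_jack1": jack.s_jack1,
                "completeness_pct": jack.completeness,
            },
            "accumulation_final": float(curve["mean"].iloc[-1]),
        }
        if len(strata) >= 2:
            mats = pd.concat(
                {k: w.to_frame().sum(axis=1) for k, w in strata.items()}, axis=1
            ).fillna(0.0).T
            multi = diversity.multi_site_bray(mats.to_numpy())
            pairs = {}
            keys = list(mats.index)
            for i in range(len(keys)):
                for j in range(i + 1, len(keys)):
                    d = diversity.bray_curtis_partition(mats.iloc[i], mats.iloc[j])
                    pairs[f"{keys[i]}|{keys[j]}"] = {
                        "total": d.total, "balanced": d.balanced, "gradient": d.gradient
                    }
            div["beta_multi"] = {
                "total": multi.total, "balanced": multi.balanced, "gradient": multi.gradient
            }
            div["beta_pairs"] = pairs
        report["diversity"] = div
        curve_out = curve

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        spec = metrics.specialization(web)
        spec.insect_dprime.to_csv(out / "insect_dprime.csv", lineterminator="\n")
        spec.host_dprime.to_csv(out / "host_dprime.csv", lineterminator="\n")
        hits = metrics.hits_scores(web)
        pd.concat([hits.hub], axis=1).to_csv(out / "hub_scores.csv", lineterminator="\n")
        pd.concat([hits.authority], axis=1).to_csv(out / "authority_scores.csv", lineterminator="\n")
        mods = report["full_network"]["modularity"]["modules"]
        pd.Series(mods, name="module").rename_axis("node").to_csv(
            out / "modules.csv", lineterminator="\n"
        )
        if records is not None and curve_out is not None:
            curve_out.to_csv(out / "accumulation_curve.csv", index=False, lineterminator="\n")
        log.info("report written to %s", out / "report.json")
    return report
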