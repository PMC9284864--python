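"""One-command orchestration of the full colony-genetics analysis.

Stages, in order: load or simulate a genotype table -> reconstruct every
colony's pedigree -> classify mating systems -> nestmate relatedness with a
t-test against the haplodiploid full-sister expectation -> F-statistics
(F_IS per site, pairwise F_ST with differentiation categories) -> the
queen-mate non-random-mating KS test (QG and ML variants) -> a structured
report (JSON + text).  All randomness fans out from one master seed via
fixed per-stage spawn keys, so re-running the same config twice produces
byte-identical reports.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import read_genotype_table
from .matingtest import MatingTestError, build_pair_sets, ks_one_sided
from .popstats import PopStatsError, classify_fst, f_statistics, one_sample_ttest
from .reconstruct import (
    CLASS_MONANDROUS,
    CLASS_MULTI_QUEEN,
    CLASS_POLYANDROUS,
    CLASS_UNDETERMINED,
    ReconstructionOptions,
    reconstruct_all,
)
from .relatedness import estimate_allele_frequencies, mean_within_group_relatedness
from .simulate import simulate_study, study_from_spec, study_from_yaml
from .tables import GenotypeTable


class PipelineError(RuntimeError):
    """A stage failed; the message carries the stage name and context."""


_STAGES = ("simulate", "frequencies", "popstats", "ks_qg", "ks_ml")


def _stage_seed(master: int, stage: str) -> int:
    idx = _STAGES.index(stage)
    ss = np.random.SeedSequence(master, spawn_key=(idx,))
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclasses.dataclass
class StudyReport:
    """Machine-readable results of one pipeline run."""

    data: dict

    def to_json(self) -> str:
        return json.dumps(self.data, indent=2, sort_keys=True, allow_nan=True)

    def to_text(self) -> str:
        d = self.data
        lines = [
            f"colonykin study report (v{d['provenance']['version']}, seed {d['provenance']['seed']})",
            "",
            f"Colonies analysed: {d['n_colonies']}",
        ]
        c = d["counts"]
        lines.append(
            f"  monandrous {c[CLASS_MONANDROUS]}, polyandrous {c[CLASS_POLYANDROUS]}, "
            f"multi-queen {c[CLASS_MULTI_QUEEN]}, undetermined {c[CLASS_UNDETERMINED]}, "
            f"alien workers {c['aliens']}"
        )
        nr = d.get("nestmate_relatedness")
        if nr:
            lines.append("")
            lines.append(
                f"Nestmate relatedness: mean {nr['mean']:.3f} +/- {nr['sd']:.3f} (SD), "
                f"SE {nr['se']:.3f}, n = {nr['n']} colonies"
            )
            if nr.get("ttest"):
                t = nr["ttest"]
                lines.append(
                    f"  vs r = {t['mu']}: t = {t['t']:.3f}, df = {t['df']}, p = {t['p']:.3f}"
                )
        fs = d.get("f_statistics")
        if fs:
            lines.append("")
            fis = fs.get("fis_overall")
            lines.append(f"F_IS overall: {fis:.3f}" if fis is not None else "F_IS overall: n/a")
            for pop, v in fs.get("fis_by_site", {}).items():
                lines.append(f"  {pop}: {'n/a' if v is None else format(v, '.3f')}")
            for row in fs.get("pairwise_fst", []):
                lines.append(
                    f"  F_ST {row['site_a']} vs {row['site_b']}: {row['fst']:.3f} ({row['category']})"
                )
        mt = d.get("mating_test")
        lines.append("")
        if mt and "skipped" in mt:
            lines.append(f"Mating test skipped: {mt['skipped']}")
        elif mt:
            for est in ("qg", "ml"):
                k = mt[est]
                perm = k["p_permutation"]
                lines.append(
                    f"Queen-mate KS ({est.upper()}): D = {k['D']:.3f}, "
                    f"asymptotic p = {k['p_asymptotic']:.4f}"
                    + (f", permutation p = {perm:.4f}" if perm is not None else "")
                    + f"  (n = {mt['n_mate_pairs']} mate pairs vs {mt['n_null_pairs']} cross pairs)"
                )
        return "\n".join(lines) + "\n"


def _load_config(config: Mapping[str, Any] | str | Path) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def run_pipeline(
    config: Mapping[str, Any] | str | Path,
    out_dir: str | Path | None = None,
) -> StudyReport:
    """Execute the full analysis described by a config mapping or YAML path.

    The config names either an input genotype table (``input: {genotypes,
    dialect}``) or a simulation spec (``simulation:`` with the schema of
    :func:`colonykin.simulate.study_from_yaml`); ``analysis:`` carries the
    knobs (frequency reference, KS permutations, reconstruction options,
    the sister-relatedness null ``sister_r``).
    """
    cfg = _load_config(config)
    seed = int(cfg.get("seed", 0))
    analysis = dict(cfg.get("analysis", {}))
    sister_r = float(analysis.get("sister_r", 0.75))
    n_perm = int(analysis.get("ks_permutations", 2000))
    freq_ref = analysis.get("frequency_reference", "per-colony-one-worker")
    recon_opts = ReconstructionOptions(
        max_aliens=int(analysis.get("max_aliens", 1)),
        allow_two_queens=bool(analysis.get("allow_two_queens", True)),
    )

    # ------------------------------------------------------------ input stage
    study = None
    if "simulation" in cfg:
        try:
            sim = cfg["simulation"]
            if isinstance(sim, (str, Path)):
                model, design, _ = study_from_yaml(sim)
            else:
                model, design, _ = study_from_spec({"seed": seed, **sim})
            study = simulate_study(model, design, seed=_stage_seed(seed, "simulate"))
            table = study.table
        except Exception as e:
            raise PipelineError(f"stage simulate: {e}") from e
    elif "input" in cfg:
        try:
            inp = cfg["input"]
            table, report = read_genotype_table(
                inp["genotypes"],
                inp.get("dialect", "csv-wide"),
                min_typed_loci=int(analysis.get("min_typed_loci", 10)),
            )
        except Exception as e:
            raise PipelineError(f"stage load: {e}") from e
    else:
        raise PipelineError("config must provide either 'simulation' or 'input'")

    workers = table.filter(caste="worker")
    colonies = workers.colonies()

    # ------------------------------------------------------ frequency reference
    try:
        if freq_ref == "true":
            if study is None:
                raise ValueError("'true' frequency reference needs a simulation input")
            model = study.model
            if model.n_sites == 1:
                freqs = model.allele_frequencies(0)
            else:
                freqs = model.ancestral_allele_frequencies()
        else:
            freqs = estimate_allele_frequencies(
                table, freq_ref, seed=_stage_seed(seed, "frequencies")
            )
    except Exception as e:
        raise PipelineError(f"stage frequencies: {e}") from e

    # --------------------------------------------------------- reconstruction
    try:
        recons = reconstruct_all(table, recon_opts)
    except Exception as e:
        raise PipelineError(f"stage reconstruct: {e}") from e
    counts = {
        CLASS_MONANDROUS: 0,
        CLASS_POLYANDROUS: 0,
        CLASS_MULTI_QUEEN: 0,
        CLASS_UNDETERMINED: 0,
        "aliens": 0,
        "heuristic": 0,
    }
    colony_rows = []
    for cid, recon in recons.items():
        counts[recon.classification] += 1
        counts["aliens"] += recon.n_aliens
        counts["heuristic"] += int(recon.heuristic)
        colony_rows.append(
            {
                "colony": cid,
                "site": workers.filter(colony=cid).meta["site"].iloc[0],
                "n_workers": len(recon.worker_ids),
                "n_queens": recon.n_queens,
                "n_fathers": recon.n_fathers,
                "n_aliens": recon.n_aliens,
                "classification": recon.classification,
                "alien_ids": sorted(recon.alien_ids),
            }
        )

    # --------------------------------------------------- nestmate relatedness
    nestmate = None
    try:
        per_colony = []
        for cid in colonies:
            if workers.filter(colony=cid).n_individuals < 2:
                continue
            g = mean_within_group_relatedness(table, cid, freqs)
            per_colony.append({"colony": cid, "mean_r": g.mean, "sd": g.sd, "n_pairs": g.n_pairs})
        if per_colony:
            means = np.array([row["mean_r"] for row in per_colony])
            nestmate = {
                "per_colony": per_colony,
                "mean": float(means.mean()),
                "sd": float(means.std(ddof=1)) if means.size > 1 else 0.0,
                "se": float(means.std(ddof=1) / np.sqrt(means.size)) if means.size > 1 else 0.0,
                "n": int(means.size),
                "mu": sister_r,
                "ttest": None,
            }
            if means.size >= 2 and means.std(ddof=1) > 0:
                t = one_sample_ttest(means, sister_r)
                nestmate["ttest"] = {"t": t.t, "df": t.df, "p": t.p, "mu": t.mu}
    except Exception as e:
        raise PipelineError(f"stage relatedness: {e}") from e

    # ------------------------------------------------------------ F-statistics
    fstats_block = None
    try:
        # one worker per colony for the population-level picture, so family
        # structure within colonies does not masquerade as inbreeding
        rng = np.random.default_rng(_stage_seed(seed, "popstats"))
        picked = []
        for cid in colonies:
            members = workers.filter(colony=cid).ids
            picked.append(members[rng.integers(len(members))])
        popsample = table.subset(picked)
        if popsample.n_individuals >= 4:
            ps = f_statistics(popsample, "site", min_per_pop=2)
            pairwise = []
            for i, a in enumerate(ps.populations):
                for b in ps.populations[i + 1:]:
                    v = ps.pairwise_fst.loc[a, b]
                    if not np.isnan(v):
                        pairwise.append(
                            {
                                "site_a": a,
                                "site_b": b,
                                "fst": float(v),
                                "category": classify_fst(float(v)),
                            }
                        )
            fstats_block = {
                "fis_overall": ps.fis,
                "theta_overall": ps.theta,
                "fis_by_site": dict(ps.fis_by_population),
                "pairwise_fst": pairwise,
                "n_individuals": popsample.n_individuals,
            }
    except PopStatsError as e:
        fstats_block = {"skipped": str(e)}
    except Exception as e:
        raise PipelineError(f"stage popstats: {e}") from e

    # ------------------------------------------------------------- mating test
    mating_block: dict[str, Any]
    try:
        mating_block = {}
        for est in ("qg", "ml"):
            pairs = build_pair_sets(recons, freqs, estimator=est)
            ks = ks_one_sided(
                pairs.mate_values,
                pairs.null_values,
                alternative="observed_greater",
                n_permutations=n_perm,
                seed=_stage_seed(seed, f"ks_{est}"),
            )
            mating_block[est] = {
                "D": ks.D,
                "p_asymptotic": ks.p_asymptotic,
                "p_permutation": ks.p_permutation,
                "n_permutations": ks.n_permutations,
            }
            mating_block["n_mate_pairs"] = pairs.n_mate_pairs
            mating_block["n_null_pairs"] = pairs.n_null_pairs
    except MatingTestError as e:
        mating_block = {"skipped": f"insufficient colonies: {e}"}
    except Exception as e:
        raise PipelineError(f"stage matingtest: {e}") from e

    # ---------------------------------------------------------------- assemble
    data = {
        "provenance": {
            "version": __version__,
            "seed": seed,
            "config": _jsonable(cfg),
            "frequency_reference": getattr(freqs, "provenance", str(freq_ref)),
        },
        "n_colonies": len(colonies),
        "counts": counts,
        "colonies": colony_rows,
        "nestmate_relatedness": nestmate,
        "f_statistics": fstats_block,
        "mating_test": mating_block,
    }
    if study is not None:
        data["truth"] = _truth_summary(study)
    report = StudyReport(data=data)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(report.to_json() + "\n")
        (out / "report.txt").write_text(report.to_text())
        pd.DataFrame(
            [{k: v for k, v in row.items() if k != "alien_ids"} for row in colony_rows]
        ).to_csv(out / "colonies.csv", index=False)
    return report


def _truth_summary(study) -> dict:
    n_poly = n_multi = n_alien_workers = 0
    for truth in study.truths.values():
        fathers_used = {
            w.father_index for w in truth.workers.values() if not w.alien and w.queen_index == 0
        }
        queens_used = {w.queen_index for w in truth.workers.values() if not w.alien}
        if len(queens_used) > 1:
            n_multi += 1
        elif len(fathers_used) > 1:
            n_poly += 1
        n_alien_workers += len(truth.alien_ids)
    return {
        "n_colonies": len(study.truths),
        "polyandrous": n_poly,
        "multi_queen": n_multi,
        "alien_workers": n_alien_workers,
    }


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (str, int, float, bool)) or obj is None:
        return obj
    return str(obj)
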