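"""End-to-end orchestration: simulate → prioritize → SV consensus → classify.

``run_all`` drives one reproducible run over a synthetic cohort bundle,
writing every stage output plus a machine-readable manifest (config
snapshot, input digests, per-stage record counts, seed, version) whose
identical inputs reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .classify import cohort_report
from .io import read_cohort
from .model import FilterConfig
from .simulate import CohortConfig, SyntheticCohort, generate, run_recovery
from .sv import read_exons, read_sv_calls, sv_consensus

__all__ = ["RunManifest", "parse_config_file", "run_all", "ConfigError"]


class ConfigError(ValueError):
    """A run/filter configuration file is malformed."""


_BOOL_KEYS = {
    "qc_apply_to_parents",
    "denovo_require_zero_parent_alt_reads",
    "missing_scores_nonblocking",
}
_INT_KEYS = {"min_reads_per_allele", "nmd_end_window_bp"}


def parse_config_file(path: str | Path) -> FilterConfig:
    """Key-value filter configuration (``name = value``, ``#`` comments).

    Keys mirror :class:`~varsieve.model.FilterConfig` field names; unknown
    keys are errors.
    """
    valid = {f.name for f in dataclasses.fields(FilterConfig)}
    kwargs: dict[str, object] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value'")
        key, raw = (part.strip() for part in line.split("=", 1))
        if key not in valid:
            raise ConfigError(f"{path}:{lineno}: unknown key {key!r}")
        if key in _BOOL_KEYS:
            kwargs[key] = raw.lower() in ("1", "true", "yes")
        elif key in _INT_KEYS:
            kwargs[key] = int(raw)
        else:
            kwargs[key] = float(raw)
    try:
        return FilterConfig(**kwargs)  # type: ignore[arg-type]
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


@dataclass
class RunManifest:
    seed: int
    version: str
    config: dict
    input_digests: dict[str, str]
    stage_counts: dict[str, int]
    results: dict

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                         sort_keys=True) + "\n")


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(
    output_dir: str | Path,
    *,
    seed: int = 0,
    filter_config: Optional[FilterConfig] = None,
    cohort_config: Optional[CohortConfig] = None,
) -> RunManifest:
    """Simulate a cohort, run every stage on the written bundle, score it.

    The bundle is written to ``output_dir`` and read back through the
    standard readers before analysis, so the run exercises the on-disk
    formats end to end.
    """
    output_dir = Path(output_dir)
    filter_config = filter_config or FilterConfig()
    cohort_config = cohort_config or CohortConfig(seed=seed)
    if cohort_config.seed != seed:
        cohort_config = dataclasses.replace(cohort_config, seed=seed)

    cohort: SyntheticCohort = generate(cohort_config)
    paths = cohort.write(output_dir)

    records, trios = read_cohort(paths["vcf"], paths["annotations"],
                                 paths["pedigree"])
    reread = SyntheticCohort(
        config=cohort.config, records=records, trios=trios, truth=cohort.truth,
        evidence=cohort.evidence, contexts=cohort.contexts,
        sv_pair_based=cohort.sv_pair_based, sv_depth_based=cohort.sv_depth_based,
        sv_parental=cohort.sv_parental, exons=cohort.exons,
    )
    verdicts, classified, summary = run_recovery(reread, filter_config)

    verdict_rows = [
        {
            "proband": v.proband_id,
            "chrom": v.key[0], "pos": v.key[1], "ref": v.key[2], "alt": v.key[3],
            "route": v.route, "filter": name, "outcome": outcome,
            "survived": v.survived,
        }
        for v in verdicts
        for name, outcome in v.outcomes
    ]
    pd.DataFrame(verdict_rows).to_csv(output_dir / "verdicts.tsv", sep="\t",
                                      index=False)
    survivors = [v for v in verdicts if v.survived]
    pd.DataFrame(
        [
            {"proband": v.proband_id, "chrom": v.key[0], "pos": v.key[1],
             "ref": v.key[2], "alt": v.key[3], "route": v.route}
            for v in survivors
        ]
    ).to_csv(output_dir / "survivors.tsv", sep="\t", index=False)

    sv_pair = read_sv_calls(paths["sv_pair_based"])
    sv_depth = read_sv_calls(paths["sv_depth_based"])
    sv_parental = read_sv_calls(paths["sv_parental"])
    exons = read_exons(paths["exons"])
    candidates = sv_consensus(sv_pair, sv_depth, sv_parental, exons,
                              pli_min=filter_config.pli_min)
    n_sv_candidates = sum(len(c) for c in candidates.values())
    pd.DataFrame(
        [
            {"sample": sample, "chrom": c.pair.chrom,
             "start": c.pair.consensus_start, "end": c.pair.consensus_end,
             "sv_type": c.pair.sv_type.value, "genes": ";".join(c.genes)}
            for sample, cands in candidates.items()
            for c in cands
        ],
        columns=["sample", "chrom", "start", "end", "sv_type", "genes"],
    ).to_csv(output_dir / "sv_candidates.tsv", sep="\t", index=False)

    probands = [t.proband_id for t in trios]
    report = cohort_report(classified, probands)
    report.to_csv(output_dir / "cohort_report.tsv", sep="\t", index=False)
    summary.per_template.to_csv(output_dir / "recovery.tsv", sep="\t",
                                index=False)

    manifest = RunManifest(
        seed=seed,
        version=__version__,
        config={
            "filter": dataclasses.asdict(filter_config),
            "cohort": {
                **{
                    k: v
                    for k, v in dataclasses.asdict(cohort_config).items()
                    if k != "plants"
                },
                "plants": [p.template for p in cohort_config.plants],
            },
        },
        input_digests={name: _digest(p) for name, p in sorted(paths.items())},
        stage_counts={
            "records": len(records),
            "verdicts": len(verdicts),
            "survivors": len(survivors),
            "classified": len(classified),
            "sv_candidates": n_sv_candidates,
        },
        results={
            "survival_sensitivity": summary.survival_sensitivity,
            "survival_specificity": summary.survival_specificity,
            "tier_accuracy": summary.tier_accuracy,
            "yield_percent": float(report["yield_percent"].iloc[0]),
        },
    )
    manifest.write(output_dir / "manifest.json")
    return manifest
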