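"""Config-driven pipeline: alignments in, scored network artifacts out.

One :class:`RunConfig` (a YAML/JSON document on disk) names the input
alignments, the cognate pair table, the contact mask (directly, or via a
template structure plus residue-to-column mappings) and the numerical
parameters; :func:`run_pipeline` executes every stage and writes the full
artifact set — fitted models, DI table, mask, specificity matrix CSVs,
selection calls, validation summary, an effective-config snapshot and a
plain-text log. Reruns from the same config reproduce identical numeric
artifacts.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .alignment_io import (
    concatenate_pairs,
    encode_alignment,
    filter_by_gap_run,
    read_alignment,
    read_pair_table,
    scramble_pairs,
    write_alignment,
    write_removal_report,
)
from .contacts import (
    interface_contacts,
    map_contacts_to_columns,
    parse_structure,
    read_mapping,
    read_mask,
    write_mask,
)
from .dca import (
    compute_weights,
    count_frequencies,
    direct_information,
    fit_mfdca,
    save_model,
    write_di_table,
)
from .errors import ConfigError, StructureError
from .export import export_csv, export_heatmap, export_matrix_csv
from .mutations import MutationSpec, rescore_after_mutation, write_mutation_report
from .scoring import (
    classify_selection,
    cognate_map_from_pairs,
    empirical_null_score,
    htcs_matrix,
    specificity_matrix,
    validation_metrics,
)


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    hk_alignment: str
    rr_alignment: str
    pair_table: str
    output_dir: str
    # mask source: either a precomputed mask TSV, or structure + mappings
    mask: str | None = None
    structure: str | None = None
    hk_chain: str | None = None
    rr_chain: str | None = None
    hk_mapping: str | None = None
    rr_mapping: str | None = None
    # parameters
    alignment_format: str = "fasta"
    identity_threshold: float = 0.8
    lam: float | None = None  # None -> lambda = M_eff
    cutoff_A: float = 12.0
    contact_metric: str = "min_heavy_atom"
    hk_max_gap_run: int = 5
    rr_max_gap_run: int = 6
    scramble_rounds: int = 25
    seed: int = 0
    null_estimator: str = "scrambled_model"  # or "empirical_repairing"
    mutations: list = field(default_factory=list)  # text specs like "hk0:12A"
    heatmap: bool = True

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        if not isinstance(raw, dict):
            raise ConfigError(f"config {path} is not a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate(base=path.parent)
        return cfg

    def validate(self, base: Path | None = None) -> None:
        base = base or Path(".")

        def resolve(p):
            p = Path(p)
            return p if p.is_absolute() else base / p

        for name in ("hk_alignment", "rr_alignment", "pair_table"):
            p = resolve(getattr(self, name))
            if not p.exists():
                raise ConfigError(f"{name} path does not exist: {p}")
            setattr(self, name, str(p))
        if self.mask is not None:
            p = resolve(self.mask)
            if not p.exists():
                raise ConfigError(f"mask path does not exist: {p}")
            self.mask = str(p)
        elif self.structure is not None:
            for name in ("structure", "hk_mapping", "rr_mapping"):
                val = getattr(self, name)
                if val is None:
                    raise ConfigError(f"structure-based mask requires {name}")
                p = resolve(val)
                if not p.exists():
                    raise ConfigError(f"{name} path does not exist: {p}")
                setattr(self, name, str(p))
        else:
            raise ConfigError("config needs either 'mask' or 'structure' (+ mappings)")
        if not 0 < self.identity_threshold <= 1:
            raise ConfigError("identity_threshold must be in (0, 1]")
        if self.cutoff_A <= 0:
            raise ConfigError("cutoff_A must be positive")
        if self.scramble_rounds < 1:
            raise ConfigError("scramble_rounds must be >= 1")
        if self.null_estimator not in ("scrambled_model", "empirical_repairing"):
            raise ConfigError(f"unknown null_estimator: {self.null_estimator!r}")
        self.output_dir = str(resolve(self.output_dir))


def _fit_from_paired(paired, identity_threshold, lam, provenance):
    enc = encode_alignment(paired.alignment)
    weights, m_eff = compute_weights(enc, identity_threshold)
    freqs = count_frequencies(enc, weights, lam)
    model = fit_mfdca(freqs, provenance=provenance)
    return model, freqs, m_eff


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full scoring pipeline; returns a dict of artifact paths."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = []
    t0 = time.time()

    def log(stage: str, **info):
        entry = f"[{time.time() - t0:8.2f}s] {stage}"
        if info:
            entry += "  " + "  ".join(f"{k}={v}" for k, v in info.items())
        log_lines.append(entry)

    log("start", version=__version__, seed=config.seed)
    (out / "effective_config.yaml").write_text(yaml.safe_dump(asdict(config), sort_keys=False))

    artifacts = {"config": str(out / "effective_config.yaml")}
    stage = "read_alignments"
    try:
        hk = read_alignment(config.hk_alignment, config.alignment_format, domain_tag="HK")
        rr = read_alignment(config.rr_alignment, config.alignment_format, domain_tag="RR")
        pairs = read_pair_table(config.pair_table)
        log(stage, hk=hk.n_rows, rr=rr.n_rows, pairs=len(pairs.pairs))

        stage = "gap_filter"
        hk, hk_removed = filter_by_gap_run(hk, config.hk_max_gap_run)
        rr, rr_removed = filter_by_gap_run(rr, config.rr_max_gap_run)
        write_removal_report(hk_removed, out / "hk_removed.tsv")
        write_removal_report(rr_removed, out / "rr_removed.tsv")
        surviving = [
            (h, r) for h, r in pairs.pairs if h in set(hk.ids) and r in set(rr.ids)
        ]
        pairs.pairs = surviving
        log(stage, hk_removed=len(hk_removed), rr_removed=len(rr_removed),
            pairs_surviving=len(surviving))

        stage = "contact_mask"
        if config.mask is not None:
            mask = read_mask(config.mask)
        else:
            chains = {c.chain_id: c for c in parse_structure(config.structure)}
            try:
                chain_a = chains[config.hk_chain]
                chain_b = chains[config.rr_chain]
            except KeyError as exc:
                raise StructureError(f"chain {exc} not found in {config.structure}") from exc
            contacts = interface_contacts(
                chain_a, chain_b, cutoff_a=config.cutoff_A, metric=config.contact_metric
            )
            mapping = read_mapping(
                config.hk_mapping, config.rr_mapping, hk.n_columns, rr.n_columns
            )
            mask, dropped = map_contacts_to_columns(
                contacts, mapping, cutoff_a=config.cutoff_A, metric_tag=config.contact_metric
            )
            log(stage + ":dropped_pairs", n=len(dropped))
        write_mask(mask, out / "mask.tsv")
        log(stage, pairs=len(mask.pairs))

        stage = "fit_cognate"
        paired = concatenate_pairs(hk, rr, pairs)
        write_alignment(paired.alignment, out / "paired_cognate.fasta")
        cognate, freqs, m_eff = _fit_from_paired(
            paired, config.identity_threshold, config.lam, "cognate"
        )
        save_model(cognate, out / "model_cognate.npz")
        log(stage, M=paired.alignment.n_rows, M_eff=f"{m_eff:.1f}")

        stage = "direct_information"
        di = direct_information(cognate, freqs)
        write_di_table(di, out / "di.tsv")
        log(stage, non_converged=len(di.non_converged))

        stage = "null_model"
        if config.null_estimator == "scrambled_model":
            scrambled = scramble_pairs(hk, rr, rounds=config.scramble_rounds, seed=config.seed)
            null, _, m_eff0 = _fit_from_paired(
                scrambled, config.identity_threshold, config.lam, "scrambled"
            )
            save_model(null, out / "model_scrambled.npz")
            log(stage, M=scrambled.alignment.n_rows, M_eff=f"{m_eff0:.1f}")
        else:
            null = None
            baseline = empirical_null_score(
                cognate, mask, hk, rr, rounds=config.scramble_rounds, seed=config.seed
            )
            log(stage, empirical_baseline=f"{baseline:.4f}")

        stage = "specificity_matrix"
        if null is not None:
            matrix = specificity_matrix(cognate, null, mask, hk, rr)
        else:
            matrix = htcs_matrix(cognate, mask, hk, rr)
            matrix.scores = matrix.scores - baseline
            matrix.model_provenance = {"cognate": "cognate", "null": "empirical_repairing"}
        export_matrix_csv(matrix, out / "specificity_matrix.csv")
        export_csv(matrix, out / "specificity_long.csv")
        log(stage, shape=f"{len(matrix.hk_ids)}x{len(matrix.rr_ids)}")

        stage = "classify"
        cmap = cognate_map_from_pairs(pairs)
        calls, skipped = classify_selection(matrix, cmap)
        with open(out / "selection_calls.tsv", "w") as fh:
            fh.write("# hk_id\trr_id\tpositive\tnegative\tverdict\n")
            for c in calls:
                fh.write(f"{c.hk_id}\t{c.rr_id}\t{int(c.positive)}\t{int(c.negative)}\t{c.verdict}\n")
        summary = validation_metrics(calls) if calls else None
        if summary is not None:
            (out / "validation_summary.json").write_text(
                json.dumps(asdict(summary), indent=2) + "\n"
            )
        log(stage, calls=len(calls), skipped=len(skipped))

        stage = "mutations"
        if config.mutations:
            if null is None:
                raise ConfigError(
                    "mutation rescoring requires null_estimator='scrambled_model'"
                )
            specs = [MutationSpec.parse(s) for s in config.mutations]
            result = rescore_after_mutation(matrix, cognate, null, mask, hk, rr, specs)
            write_mutation_report(result, out / "mutation_report.tsv")
            export_csv(result.mutated_matrix, out / "specificity_long_mutated.csv")
            log(stage, specs=len(specs))

        stage = "export"
        if config.heatmap and matrix.scores.size:
            export_heatmap(matrix, out / "heatmap.png")
        log(stage)
    except Exception as exc:
        log(f"FAILED at stage {stage}", error=repr(exc))
        (out / "run.log").write_text("\n".join(log_lines) + "\n")
        raise

    log("done")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    for p in out.iterdir():
        artifacts[p.name] = str(p)
    return artifacts
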