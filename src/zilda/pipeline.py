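"""End-to-end orchestration: ingest/simulate -> differential -> diversity ->
networks -> classifier, with one seed, structured logging to stderr, and a
checksum manifest of every output file."""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import crossval_auc, select_features_from_differential
from .diversity import (
    crc_logit_from_diversity,
    diversity_table,
    dunn_posthoc,
    kruskal_test,
    three_state_groups,
)
from .network import NetworkConfig, build_network, compare_networks, write_edges, write_graphml
from .simulate import SimConfig, simulate_study, truth_frame
from .tables import (
    GROUPS,
    CountTable,
    SampleMetadata,
    group_map,
    read_count_table,
    read_metadata,
    samples_in_group,
    to_relative_abundance,
    write_commented_tsv,
    write_count_table,
    write_metadata,
)
from .zil import run_differential

log = logging.getLogger("zilda")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    out_dir: Path
    seed: int
    table_path: Path | None = None
    metadata_path: Path | None = None
    sim: SimConfig | None = None
    group_a: str = "healthy"
    group_b: str = "crc"
    fdr_level: float = 0.05
    divisor_strategy: str = "min_variance"
    network: NetworkConfig = NetworkConfig()
    n_folds: int = 5
    max_features: int = 9
    logit_mode: str = "healthy-vs-crc"

    def __post_init__(self) -> None:
        has_paths = self.table_path is not None or self.metadata_path is not None
        if has_paths and self.sim is not None:
            raise PipelineError("give either input paths or a simulation config, not both")
        if not has_paths and self.sim is None:
            raise PipelineError("give input paths or a simulation config")
        if has_paths and (self.table_path is None or self.metadata_path is None):
            raise PipelineError("both table_path and metadata_path are required")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_all(config: PipelineConfig) -> dict[str, str]:
    """Run every stage; return {relative filename: sha256}.

    A stage failure raises :class:`PipelineError` naming the stage; files
    already written stay on disk and are flagged in the manifest with a
    ``partial`` marker row.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    stamp = f"zilda {__version__} seed={config.seed}"

    def record(name: str) -> None:
        manifest[name] = _sha256(out / name)

    stage = "input"
    try:
        if config.sim is not None:
            log.info("stage input: simulating synthetic study")
            table, metadata, truth = simulate_study(config.sim)
            write_count_table(table, out / "counts.tsv", comment=f"{stamp} synthetic counts")
            write_metadata(metadata, out / "metadata.tsv", comment=f"{stamp} synthetic metadata")
            write_commented_tsv(truth_frame(truth), out / "truth.tsv", f"{stamp} ground truth")
            record("counts.tsv")
            record("metadata.tsv")
            record("truth.tsv")
        else:
            log.info("stage input: reading %s", config.table_path)
            table = read_count_table(config.table_path)
            metadata = read_metadata(config.metadata_path)

        stage = "differential"
        log.info("stage differential: %s vs %s", config.group_a, config.group_b)
        diff = run_differential(
            table,
            metadata,
            config.group_a,
            config.group_b,
            fdr_level=config.fdr_level,
            divisor_strategy=config.divisor_strategy,
        )
        diff.write(out / "diff.tsv", version=__version__)
        record("diff.tsv")

        stage = "diversity"
        log.info("stage diversity")
        div = diversity_table(table, metadata)
        write_commented_tsv(div, out / "diversity.tsv", f"{stamp} per-sample alpha diversity")
        record("diversity.tsv")
        groups3 = three_state_groups(div)
        if len(groups3) >= 2 and all(len(v) >= 2 for v in groups3.values()):
            h, p_kw = kruskal_test(groups3)
            comp = dunn_posthoc(groups3)
            comment = f"{stamp} Dunn post-hoc (Kruskal-Wallis H={h:.6g}, p={p_kw:.6g})"
        else:
            comp = pd.DataFrame(
                columns=["group_a", "group_b", "z", "p", "p_adjusted", "method"]
            )
            comment = f"{stamp} too few states for a comparison"
        write_commented_tsv(comp, out / "comparisons.tsv", comment)
        record("comparisons.tsv")
        try:
            fit = crc_logit_from_diversity(div, mode=config.logit_mode)
            logit_df = pd.DataFrame(
                [
                    {
                        "slope": fit.slope,
                        "intercept": fit.intercept,
                        "se_slope": fit.se_slope,
                        "se_intercept": fit.se_intercept,
                        "p_slope": fit.p_slope,
                        "converged": fit.converged,
                    }
                ]
            )
            write_commented_tsv(
                logit_df, out / "logit.tsv", f"{stamp} diversity-disease logit ({config.logit_mode})"
            )
            record("logit.tsv")
        except ValueError as exc:
            log.warning("diversity logit skipped: %s", exc)

        stage = "network"
        log.info("stage network")
        gm = group_map(metadata)
        networks = []
        for state in GROUPS:
            sids = [s for s in table.sample_ids if gm.get(s) == state]
            if len(sids) < 3:
                log.warning("state %s has < 3 samples; skipping its network", state)
                continue
            sub = table.subset_samples(sids)
            networks.append(build_network(sub, config.network, state))
        if not networks:
            raise PipelineError("no state has enough samples for a network")
        write_edges(
            networks,
            out / "edges.tsv",
            f"{stamp} method={config.network.method} threshold={config.network.threshold}",
        )
        record("edges.tsv")
        write_graphml(networks, out / "networks.graphml")
        record("networks.graphml")
        if len(networks) >= 2:
            comparison = compare_networks(networks)
            write_commented_tsv(
                comparison.totals, out / "network_totals.tsv", f"{stamp} edge totals"
            )
            record("network_totals.tsv")

        stage = "classify"
        log.info("stage classify")
        features = select_features_from_differential(diff, max_features=config.max_features)
        sa = samples_in_group(metadata, config.group_a)
        sb = samples_in_group(metadata, config.group_b)
        sa = [s for s in table.sample_ids if s in set(sa)]
        sb = [s for s in table.sample_ids if s in set(sb)]
        rel = to_relative_abundance(table.subset_samples(sa + sb))
        sub = rel.subset_features(features)
        labels = np.array([0] * len(sa) + [1] * len(sb))
        cv = crossval_auc(sub, labels, n_folds=config.n_folds, seed=config.seed)
        write_commented_tsv(
            cv.frame(),
            out / "cv.tsv",
            f"{stamp} random forest, features={','.join(features)}, folds={config.n_folds}",
        )
        record("cv.tsv")
    except PipelineError:
        _write_manifest(manifest, out, complete=False)
        raise
    except Exception as exc:
        _write_manifest(manifest, out, complete=False)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    _write_manifest(manifest, out, complete=True)
    manifest["manifest.tsv"] = _sha256(out / "manifest.tsv")
    return manifest


def _write_manifest(manifest: dict[str, str], out: Path, complete: bool) -> None:
    frame = pd.DataFrame(
        {"file": list(manifest), "sha256": [manifest[k] for k in manifest]}
    )
    status = "complete" if complete else "partial"
    write_commented_tsv(frame, out / "manifest.tsv", f"zilda {__version__} manifest ({status})")
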