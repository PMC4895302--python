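"""End-to-end orchestration: extract -> label -> reduce -> encode ->
select -> tune -> cross-validate -> fit -> test, plus prediction on new
sequences.

Every run is fully determined by a :class:`RunConfig` (loadable from
YAML) and writes a resolved copy of that config next to its outputs for
provenance. Stage-level logging records record counts throughout.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import dataset as ds
from . import encoders as enc
from . import evaluation as ev
from . import model as md
from . import selection as sel
from .io_formats import (
    filter_aaindex,
    read_aaindex,
    read_fasta,
    read_pssm,
    read_sites,
    read_tracks,
)

logger = logging.getLogger(__name__)


@dataclass
class SelectionSettings:
    enabled: bool = False
    top_k_fscore: int = 20  # properties kept after F-score screening
    top_k_rank: int = 20    # properties entering forward selection
    mode: str = "cumulative"


@dataclass
class RunConfig:
    fasta: str = ""
    sites: str = ""
    aaindex: str | None = None
    pssm_dir: str | None = None
    asa: str | None = None
    ss: str | None = None
    window_n: int = 10
    encoders: list[str] = field(default_factory=lambda: ["binary"])
    identity_threshold: float = 0.30
    reduce: bool = True
    test_fraction: float = 0.2
    selection: SelectionSettings = field(default_factory=SelectionSettings)
    grid: dict = field(default_factory=lambda: {"C": [1.0, 8.0], "gamma": [0.003, 0.03]})
    class_weighting: str = "balanced"
    cv_k: int = 5
    seed: int = 1
    outdir: str = "cyspred_run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        selection = SelectionSettings(**raw.pop("selection", {}))
        return cls(selection=selection, **raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunResult:
    model: md.TrainedModel
    cv_report: ev.MetricsReport
    fold_reports: list[ev.MetricsReport]
    test_report: ev.MetricsReport | None
    svm_config: md.SVMConfig
    trace: sel.SelectionTrace | None
    feature_names: tuple


def _load_inputs(config: RunConfig):
    proteins = read_fasta(config.fasta)
    sites = read_sites(config.sites, proteins)
    aaindex = None
    if config.aaindex:
        aaindex = {e.accession: e for e in filter_aaindex(read_aaindex(config.aaindex))}
    profiles = None
    if config.pssm_dir:
        profiles = {}
        by_id = {p.id: p for p in proteins}
        for path in sorted(Path(config.pssm_dir).glob("*.pssm")):
            pid = path.stem
            expected = len(by_id[pid]) if pid in by_id else None
            profiles[pid] = read_pssm(path, pid, expected)
    asa_tracks = read_tracks(config.asa, "ASA") if config.asa else None
    ss_tracks = read_tracks(config.ss, "SS") if config.ss else None
    return proteins, sites, aaindex, profiles, asa_tracks, ss_tracks


def _build_encoders(config: RunConfig, names, pwm, profiles, aaindex,
                    asa_tracks, ss_tracks):
    resolved = []
    for name in names:
        resolved.append(
            (
                name,
                enc.make_encoder(
                    name,
                    pwm=pwm,
                    profiles=profiles,
                    aaindex=aaindex,
                    asa_tracks=asa_tracks,
                    ss_tracks=ss_tracks,
                ),
            )
        )
    return resolved


def _encode_all(fragments, encoder_list):
    blocks = []
    names: list[str] = []
    for _, encoder in encoder_list:
        X, block_names = enc.encode_matrix(fragments, encoder)
        blocks.append(X)
        names.extend(block_names)
    if len(set(names)) != len(names):
        raise ValueError("duplicate feature names across encoders")
    return np.hstack(blocks), tuple(names)


def run_train(config: RunConfig) -> RunResult:
    """Run the full training pipeline and write reports under
    ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

    proteins, sites, aaindex, profiles, asa_tracks, ss_tracks = _load_inputs(config)
    logger.info("loaded %d proteins, %d sites", len(proteins), len(sites))

    fragments = []
    for protein in proteins:
        fragments.extend(ds.extract_fragments(protein, config.window_n))
    logger.info("extracted %d fragments", len(fragments))
    fragments = ds.label_fragments(fragments, sites)

    if 0 < config.test_fraction < 1:
        split = ds.split_dataset(fragments, config.test_fraction, config.seed)
    else:
        split = ds.DatasetSplit(list(fragments), [])
    logger.info("split: %d train / %d test", len(split.train), len(split.test))

    if config.reduce:
        split = ds.reduce_homology(
            split, proteins, threshold=config.identity_threshold
        )
        logger.info(
            "after homology reduction: %d train / %d test",
            len(split.train), len(split.test),
        )
    ds.write_fragments(split.train, outdir / "fragments_train.tsv")
    ds.write_fragments(split.test, outdir / "fragments_test.tsv")

    pwm = None
    if "pwm" in config.encoders:
        positives = [f for f in split.train if f.label == 1]
        pwm = enc.build_pwm(positives)
    encoder_list = _build_encoders(
        config, config.encoders, pwm, profiles, aaindex, asa_tracks, ss_tracks
    )
    X_train, names = _encode_all(split.train, encoder_list)
    y_train = np.array([f.label for f in split.train])
    logger.info("encoded training matrix %s", X_train.shape)

    cv = ev.CVConfig(k=config.cv_k, seed=config.seed)
    selected_properties: list[str] = []
    trace = None
    if config.selection.enabled:
        if aaindex is None:
            raise ValueError("selection requires an AAindex file")
        table = sel.score_properties(split.train, list(aaindex.values()))
        top = [name for name, _ in table.ranked()[: config.selection.top_k_fscore]]
        table.write_tsv(outdir / "fscore_table.tsv")
        svm_screen = md.SVMConfig(class_weighting=config.class_weighting)
        ranked = sel.rank_by_single_accuracy(
            [aaindex[a] for a in top], split.train, svm_screen, cv
        )
        ranked = ranked[: config.selection.top_k_rank]
        candidates = []
        for rp in ranked:
            Xp, _ = enc.encode_matrix(
                split.train, lambda f, e=rp.entry: enc.encode_aaindex(f, e)
            )
            candidates.append((f"aaindex:{rp.entry.accession}", Xp))
        trace = sel.forward_select(
            X_train, candidates, y_train, svm_screen, cv,
            mode=config.selection.mode,
        )
        trace.write_tsv(outdir / "selection_trace.tsv")
        selected_properties = [n.split(":", 1)[1] for n in trace.best_prefix]
        logger.info("forward selection kept %s", selected_properties or "(none)")
        for accession in selected_properties:
            Xp, prop_names = enc.encode_matrix(
                split.train,
                lambda f, e=aaindex[accession]: enc.encode_aaindex(f, e),
            )
            X_train = np.hstack([X_train, Xp])
            names = tuple(list(names) + list(prop_names))

    svm_config, cv_report = md.grid_search(
        X_train, y_train, config.grid, cv, class_weighting=config.class_weighting
    )
    logger.info("grid search chose C=%g gamma=%g (pooled MCC %.3f)",
                svm_config.C, svm_config.gamma, cv_report.mcc)
    pooled, fold_reports = ev.cross_validate(X_train, y_train, svm_config, cv)

    final_model = md.train_svm(X_train, y_train, svm_config, feature_names=names)

    test_report = None
    if split.test:
        X_test, test_names = _encode_all(split.test, encoder_list)
        if selected_properties:
            for accession in selected_properties:
                Xp, prop_names = enc.encode_matrix(
                    split.test,
                    lambda f, e=aaindex[accession]: enc.encode_aaindex(f, e),
                )
                X_test = np.hstack([X_test, Xp])
        y_test = np.array([f.label for f in split.test])
        test_report = ev.independent_test(final_model, X_test, y_test)

    report = {
        "svm": {"C": svm_config.C, "gamma": svm_config.gamma,
                "class_weighting": svm_config.class_weighting},
        "pooled": pooled.as_dict(),
        "folds": [r.as_dict() for r in fold_reports],
        "selected_properties": selected_properties,
        "n_train": len(split.train),
        "n_test": len(split.test),
    }
    if test_report is not None:
        report["independent_test"] = test_report.as_dict()
    with open(outdir / "cv_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")

    extra = {
        "encoders": list(config.encoders),
        "selected_properties": selected_properties,
        "window_n": config.window_n,
        "pwm": pwm,
        "aaindex": aaindex,
    }
    md.save_model(final_model, outdir / "model.joblib", extra=extra)
    return RunResult(
        model=final_model,
        cv_report=pooled,
        fold_reports=fold_reports,
        test_report=test_report,
        svm_config=svm_config,
        trace=trace,
        feature_names=names,
    )


def run_predict(
    model_path,
    fasta_path,
    pssm_dir=None,
    asa_path=None,
    ss_path=None,
    out_path=None,
) -> list[tuple[str, int, float, int]]:
    """Predict every cysteine of the given proteins with a saved model.

    Returns (protein_id, position, decision_value, label) rows; missing
    profiles/tracks required by the model's encoder manifest are errors.
    """
    model, extra = md.load_model(model_path)
    proteins = read_fasta(fasta_path)
    window_n = extra["window_n"]
    encoder_names = list(extra["encoders"]) + [
        f"aaindex:{a}" for a in extra.get("selected_properties", [])
    ]

    profiles = None
    if "pssm" in encoder_names:
        if pssm_dir is None:
            raise ValueError("model requires encoder 'pssm' but no PSSM "
                             "directory was given")
        profiles = {}
        by_id = {p.id: p for p in proteins}
        for path in sorted(Path(pssm_dir).glob("*.pssm")):
            pid = path.stem
            expected = len(by_id[pid]) if pid in by_id else None
            profiles[pid] = read_pssm(path, pid, expected)
    asa_tracks = None
    if "asa" in encoder_names:
        if asa_path is None:
            raise ValueError("model requires encoder 'asa' but no ASA track "
                             "file was given")
        asa_tracks = read_tracks(asa_path, "ASA")
    ss_tracks = None
    if "ss" in encoder_names:
        if ss_path is None:
            raise ValueError("model requires encoder 'ss' but no SS track "
                             "file was given")
        ss_tracks = read_tracks(ss_path, "SS")

    encoder_list = []
    for name in encoder_names:
        encoder_list.append(
            (
                name,
                enc.make_encoder(
                    name,
                    pwm=extra.get("pwm"),
                    profiles=profiles,
                    aaindex=extra.get("aaindex"),
                    asa_tracks=asa_tracks,
                    ss_tracks=ss_tracks,
                ),
            )
        )

    rows: list[tuple[str, int, float, int]] = []
    fragments = []
    for protein in proteins:
        fragments.extend(ds.extract_fragments(protein, window_n))
    if fragments:
        X, names = _encode_all(fragments, encoder_list)
        labels, decisions = md.predict(model, X, names)
        # decision sign convention: positive decision favors +1
        sign = 1.0 if model.classifier.classes_[1] == 1 else -1.0
        for frag, label, decision in zip(fragments, labels, decisions):
            rows.append(
                (frag.protein_id, frag.center_position,
                 float(sign * decision), int(label))
            )
    if out_path is not None:
        with open(out_path, "w") as fh:
            fh.write("protein_id\tposition\tdecision_value\tpredicted_label\n")
            for pid, pos, decision, label in rows:
                fh.write(f"{pid}\t{pos}\t{decision:.6f}\t{label:+d}\n")
    return rows
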