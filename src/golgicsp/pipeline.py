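"""End-to-end orchestration: extract -> fuse -> balance -> select -> evaluate.

A :class:`PipelineConfig` names the feature blocks to concatenate, in a
fixed order so feature indices stay stable across runs:

    gapDC (400) | CSP-PSSM-DC (20) | CSP-BIGRAM (20) | CSP-ED (20)

with the raw 400-dimensional PSSM-DC / BIGRAM / ED blocks also available
for ablations.  The default fusion (gapDC + three CSP blocks) is 460 wide.

Cross-validation is leakage-safe by default: the CSP projections, SMOTE
balancing and any feature selection are refitted inside each training
fold.  ``paper_mode`` instead fits the CSP projections and applies SMOTE
on the full dataset before splitting, mirroring the common (optimistic)
reading of published protocols of this kind.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .classify_eval import EvalReport, ForestSpec, cross_validate
from .csp_transform import CSPModel, csp_feature_names, csp_features, fit_csp
from .feature_selection import rf_rfe, select_optimal_prefix
from .imbalance import LabeledFeatureTable, smote_balance
from .pssm_features import (
    KIND_BIGRAM,
    KIND_ED,
    KIND_PSSM_DC,
    PSSMProfile,
    bigram_pssm,
    ed_pssm,
    evo_feature_names,
    flatten_evo_matrix,
    pssm_dc,
    read_ascii_pssm,
)
from .seq_features import (
    ProteinSequence,
    gap_dc_feature_names,
    gap_dipeptide_composition,
    read_fasta,
)

__all__ = [
    "PipelineConfig",
    "build_feature_table",
    "evaluate_dataset",
    "run_pipeline",
    "load_dataset",
    "BLOCK_ORDER",
]

#: canonical block order (stable feature indices)
BLOCK_ORDER = (
    "gapDC",
    "CSP-PSSM-DC",
    "CSP-BIGRAM",
    "CSP-ED",
    "PSSM-DC",
    "BIGRAM",
    "ED",
)
_CSP_BLOCK_KIND = {
    "CSP-PSSM-DC": KIND_PSSM_DC,
    "CSP-BIGRAM": KIND_BIGRAM,
    "CSP-ED": KIND_ED,
}
_RAW_BLOCK_KIND = {"PSSM-DC": KIND_PSSM_DC, "BIGRAM": KIND_BIGRAM, "ED": KIND_ED}
_EXTRACTOR = {KIND_PSSM_DC: pssm_dc, KIND_BIGRAM: bigram_pssm, KIND_ED: ed_pssm}


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to reproduce one run."""

    g: int = 3
    blocks: tuple[str, ...] = ("gapDC", "CSP-PSSM-DC", "CSP-BIGRAM", "CSP-ED")
    smote: bool = True
    smote_k: int = 5
    select: bool = False
    folds: int = 10
    jackknife: bool = False
    n_trees: int = 100
    m_try: int | None = None
    stratified: bool = True
    paper_mode: bool = False
    pssm_scale: str = "raw"
    csp_orientation: str = "paper"
    strict_missing_pssm: bool = True
    seed: int = 0
    input_dir: str | None = None
    output_dir: str = "golgicsp_out"

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("at least one feature block is required")
        unknown = set(self.blocks) - set(BLOCK_ORDER)
        if unknown:
            raise ValueError(f"unknown feature blocks: {sorted(unknown)}")
        if not 0 <= self.g <= 8:
            raise ValueError("g must be in [0, 8]")

    @property
    def ordered_blocks(self) -> tuple[str, ...]:
        return tuple(b for b in BLOCK_ORDER if b in self.blocks)

    def forest_spec(self) -> ForestSpec:
        return ForestSpec(n_trees=self.n_trees, m_try=self.m_try, seed=self.seed)

    # -- serialization ------------------------------------------------------
    def to_yaml(self, path) -> None:
        d = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "blocks" in d:
            d["blocks"] = tuple(d["blocks"])
        return cls(**d)


# --------------------------------------------------------------------------
# Ingredients: per-protein raw material each block needs
# --------------------------------------------------------------------------

@dataclass
class _Ingredients:
    ids: list[str]
    labels: np.ndarray
    gapdc: np.ndarray | None                  # (n, 400)
    evo: dict[str, list]                      # kind -> list of EvoMatrix


def _prepare_ingredients(
    config: PipelineConfig,
    seqs: list[ProteinSequence],
    pssms: dict[str, PSSMProfile] | None,
    labels,
) -> _Ingredients:
    labels = np.asarray(labels, int)
    if len(labels) != len(seqs):
        raise ValueError("labels length must match number of sequences")
    blocks = config.ordered_blocks
    need_pssm = any(b != "gapDC" for b in blocks)
    kinds = sorted(
        {_CSP_BLOCK_KIND.get(b) or _RAW_BLOCK_KIND.get(b) for b in blocks}
        - {None}
    )
    keep: list[int] = []
    for i, s in enumerate(seqs):
        if need_pssm and (pssms is None or s.id not in pssms):
            msg = f"no PSSM profile for protein {s.id!r}"
            if config.strict_missing_pssm:
                raise ValueError(msg)
            warnings.warn(msg + "; skipping", stacklevel=2)
            continue
        keep.append(i)
    seqs = [seqs[i] for i in keep]
    labels = labels[keep]

    gapdc = None
    if "gapDC" in blocks:
        gapdc = np.stack(
            [gap_dipeptide_composition(s, config.g).values for s in seqs]
        )
    evo: dict[str, list] = {}
    for kind in kinds:
        evo[kind] = [
            _EXTRACTOR[kind](pssms[s.id], scale=config.pssm_scale) for s in seqs
        ]
    return _Ingredients(
        ids=[s.id for s in seqs], labels=labels, gapdc=gapdc, evo=evo
    )


def _fit_models(
    config: PipelineConfig, ing: _Ingredients, rows: np.ndarray
) -> dict[str, CSPModel]:
    models: dict[str, CSPModel] = {}
    for block in config.ordered_blocks:
        kind = _CSP_BLOCK_KIND.get(block)
        if kind is None:
            continue
        mats = ing.evo[kind]
        pos = [mats[i] for i in rows if ing.labels[i] == 1]
        neg = [mats[i] for i in rows if ing.labels[i] == 0]
        models[block] = fit_csp(pos, neg, orientation=config.csp_orientation)
    return models


def _assemble(
    config: PipelineConfig,
    ing: _Ingredients,
    rows: np.ndarray,
    models: dict[str, CSPModel],
) -> np.ndarray:
    parts: list[np.ndarray] = []
    for block in config.ordered_blocks:
        if block == "gapDC":
            parts.append(ing.gapdc[rows])
        elif block in _CSP_BLOCK_KIND:
            kind = _CSP_BLOCK_KIND[block]
            model = models[block]
            parts.append(
                np.stack([csp_features(model, ing.evo[kind][i]) for i in rows])
            )
        else:
            kind = _RAW_BLOCK_KIND[block]
            parts.append(
                np.stack([flatten_evo_matrix(ing.evo[kind][i]) for i in rows])
            )
    return np.hstack(parts)


def _feature_names(config: PipelineConfig) -> tuple[str, ...]:
    names: list[str] = []
    for block in config.ordered_blocks:
        if block == "gapDC":
            names += gap_dc_feature_names(config.g)
        elif block in _CSP_BLOCK_KIND:
            names += csp_feature_names(_CSP_BLOCK_KIND[block])
        else:
            names += evo_feature_names(_RAW_BLOCK_KIND[block])
    return tuple(names)


def build_feature_table(
    config: PipelineConfig,
    seqs: list[ProteinSequence],
    pssms: dict[str, PSSMProfile] | None,
    labels,
    csp_models: dict[str, CSPModel] | None = None,
) -> tuple[LabeledFeatureTable, dict[str, CSPModel]]:
    """Concatenate the configured feature blocks for every protein.

    CSP blocks need fitted projections; when ``csp_models`` is not
    supplied they are fitted on all the data passed in (appropriate for
    final-model training or ``paper_mode``, not for leakage-safe CV —
    :func:`run_pipeline` handles the per-fold case).
    """
    ing = _prepare_ingredients(config, seqs, pssms, labels)
    rows = np.arange(len(ing.ids))
    models = csp_models if csp_models is not None else _fit_models(config, ing, rows)
    X = _assemble(config, ing, rows, models)
    table = LabeledFeatureTable(
        X=X,
        y=ing.labels,
        feature_names=_feature_names(config),
        ids=tuple(ing.ids),
    )
    return table, models


def load_dataset(input_dir):
    """Load sequences.fasta, pssm/<id>.pssm and labels.csv from a directory."""
    d = Path(input_dir)
    seqs = read_fasta(d / "sequences.fasta")
    labels_by_id: dict[str, int] = {}
    with open(d / "labels.csv") as fh:
        header = fh.readline()
        if not header.lower().startswith("id,"):
            raise ValueError(f"{d / 'labels.csv'}: expected 'id,label' header")
        for line in fh:
            if line.strip():
                pid, lab = line.strip().split(",")
                labels_by_id[pid] = int(lab)
    labels = [labels_by_id[s.id] for s in seqs]
    pssm_dir = d / "pssm"
    pssms = None
    if pssm_dir.is_dir():
        pssms = {p.stem: read_ascii_pssm(p) for p in sorted(pssm_dir.glob("*.pssm"))}
    return seqs, pssms, np.asarray(labels, int)


def evaluate_dataset(
    config: PipelineConfig,
    seqs: list[ProteinSequence],
    pssms: dict[str, PSSMProfile] | None,
    labels,
) -> EvalReport:
    """Cross-validate the configured pipeline on a dataset (no artifacts).

    In the default leakage-safe protocol the CSP projections, SMOTE and any
    feature selection are refitted on the training portion of every fold;
    ``paper_mode`` fits CSP and applies SMOTE once on the full dataset
    before splitting.
    """
    ing = _prepare_ingredients(config, seqs, pssms, labels)
    n = len(ing.ids)
    folds = n if config.jackknife else config.folds
    forest = config.forest_spec()
    names = _feature_names(config)

    select_hook = None
    if config.select:
        def select_hook(train_tab: LabeledFeatureTable, seed: int) -> list[str]:
            rank = rf_rfe(train_tab, seed, forest=forest)
            k, _curve = select_optimal_prefix(
                train_tab, rank, folds=min(5, folds), seed=seed, forest=forest
            )
            return list(rank.top(k))

    if config.paper_mode:
        # fit CSP on everything, balance once, then split
        table, models = build_feature_table(config, seqs, pssms, labels)
        if config.smote:
            table = smote_balance(table, k=config.smote_k, seed=config.seed)
        report = cross_validate(
            table,
            folds=(table.n if config.jackknife else folds),
            seed=config.seed,
            forest=forest,
            smote=False,
            stratified=config.stratified,
            select_features=select_hook,
        )
    else:
        base = LabeledFeatureTable(
            X=np.zeros((n, 1)),
            y=ing.labels,
            feature_names=("placeholder",),
            ids=tuple(ing.ids),
        )

        def fold_features(tr: np.ndarray, te: np.ndarray):
            models = _fit_models(config, ing, tr)
            X_train = _assemble(config, ing, tr, models)
            X_test = _assemble(config, ing, te, models)
            train_tab = LabeledFeatureTable(
                X=X_train,
                y=ing.labels[tr],
                feature_names=names,
                ids=tuple(ing.ids[i] for i in tr),
            )
            return train_tab, X_test

        report = cross_validate(
            base,
            folds=folds,
            seed=config.seed,
            forest=forest,
            smote=config.smote,
            smote_k=config.smote_k,
            stratified=config.stratified,
            fold_features=fold_features,
            select_features=select_hook,
        )
    return report


def run_pipeline(
    config: PipelineConfig,
    seqs: list[ProteinSequence] | None = None,
    pssms: dict[str, PSSMProfile] | None = None,
    labels=None,
    output_dir=None,
) -> EvalReport:
    """Run the full pipeline and write artifacts; returns the evaluation.

    Inputs may be passed directly or loaded from ``config.input_dir``.
    Reruns with the same config and seed are bit-identical.
    """
    if seqs is None:
        if config.input_dir is None:
            raise ValueError("no input data: pass seqs/labels or set input_dir")
        seqs, pssms, labels = load_dataset(config.input_dir)
    report = evaluate_dataset(config, seqs, pssms, labels)
    # full-data table and CSP models for the artifact record
    table, models = build_feature_table(config, seqs, pssms, labels)
    outdir = Path(output_dir if output_dir is not None else config.output_dir)
    _write_artifacts(config, outdir, table, models, report, config.forest_spec())
    return report


def _write_artifacts(config, outdir: Path, table, models, report, forest) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    table.to_csv(outdir / "features.csv")
    for block, model in models.items():
        model.save(outdir / f"csp_{block}.json")
    (outdir / "report.json").write_text(json.dumps(report.to_dict(), indent=2))
    (outdir / "report.txt").write_text(report.to_text() + "\n")
    np.savetxt(
        outdir / "roc.csv",
        report.roc,
        delimiter=",",
        header="fpr,tpr",
        comments="",
    )
    _plot_roc(report, outdir / "roc.png")
    if config.select:
        # rank list on the full (balanced) table, for inspection
        tab = table
        if config.smote:
            tab = smote_balance(tab, k=config.smote_k, seed=config.seed)
        rank = rf_rfe(tab, config.seed, forest=forest)
        k, curve = select_optimal_prefix(
            tab, rank, folds=min(5, config.folds), seed=config.seed, forest=forest
        )
        with open(outdir / "ranklist.csv", "w") as fh:
            fh.write("rank,feature\n")
            for i, name in enumerate(rank.names, start=1):
                fh.write(f"{i},{name}\n")
        np.savetxt(
            outdir / "accuracy_curve.csv",
            np.column_stack([np.arange(1, len(curve) + 1), curve]),
            delimiter=",",
            header="k,accuracy",
            comments="",
        )
        (outdir / "selected_k.txt").write_text(f"{k}\n")
        _plot_accuracy_curve(curve, k, outdir / "accuracy_curve.png")
    with open(outdir / "run_log.txt", "w") as fh:
        import sklearn

        fh.write(f"golgicsp run\nseed={config.seed}\n")
        fh.write(f"blocks={','.join(config.ordered_blocks)}\n")
        fh.write(f"n={table.n} features={table.n_features}\n")
        fh.write(f"numpy={np.__version__} sklearn={sklearn.__version__}\n")


def _plot_roc(report: EvalReport, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(report.roc[:, 0], report.roc[:, 1], lw=1.5,
            label=f"AUC = {report.auc:.3f}")
    ax.plot([0, 1], [0, 1], ls="--", lw=0.8, color="grey")
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_accuracy_curve(curve: np.ndarray, k_best: int, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ks = np.arange(1, len(curve) + 1)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(ks, curve, lw=1.2)
    ax.axvline(k_best, ls="--", lw=0.8, color="red",
               label=f"k* = {k_best}, Acc = {curve[k_best - 1]:.3f}")
    ax.set_xlabel("number of top-ranked features")
    ax.set_ylabel("cross-validated accuracy")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
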