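"""Experiment orchestration: the reducer x regressor comparison grid, the
physics-features-vs-raw-variables ablation, and the monomial
parameter-recovery study.

Feature pathways
----------------
* ``BP`` — physics pathway.  Models are trained on the standardized
  log pi-groups and predict the log of the dependent group (the
  effluent/influent carbon ratio); predictions are exponentiated and
  back-transformed to dimensional effluent carbon before scoring.  The
  LR family here is the monomial power-law model fitted by log-log OLS.
* ``PCA`` / ``KPCA`` / ``Autoencoder`` — data-driven pathways.  The
  standardized log raw independent variables are reduced to 4 features
  (re-standardized) which predict the log effluent concentration; the
  LR family is ridge regression (CV-selected alpha, no intercept on
  standardized features).

All positive physical quantities enter models through logarithms: the
pi-groups and raw variables are sampled/observed over several decades,
so standardizing their logs (rather than their linear values) is what
makes zero-mean/unit-variance inputs informative across scales.  All
metrics are computed on the dimensional effluent concentration so the
pathways are compared on a common scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import dataio, models, reducers, synthetic
from .dataio import SplitSpec, apply_standardizer, fit_standardizer
from .dimensions import PiBasis, construct_pi_basis, evaluate_pi
from .evaluation import EvaluationReport, aggregate_seeds, pearson_r, r_squared, smape
from .models import EnsembleConfig, FFNNConfig

__all__ = [
    "ExperimentConfig",
    "run_comparison",
    "ablation_experiment",
    "structural_surrogate",
    "monomial_recovery",
]

logger = logging.getLogger(__name__)

_ENSEMBLE_KINDS = {"GBR": "gbr", "RFR": "rfr", "SVR": "svr"}


@dataclass
class ExperimentConfig:
    """Knobs of a comparison run."""

    reducers: tuple[str, ...] = ("BP", "PCA", "KPCA", "Autoencoder")
    families: tuple[str, ...] = ("NN", "LR", "GBR", "RFR", "SVR")
    ffnn: FFNNConfig = field(default_factory=FFNNConfig)
    ae_max_epochs: int = 500


def _standardize_reduced(
    ztr: pd.DataFrame, zte: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """Center/scale reducer outputs on training statistics.

    Unlike physical features, a latent column may be constant (a dead
    ReLU unit in the autoencoder bottleneck); such columns carry no
    information and are left centered with unit scale instead of raising.
    """
    mean = ztr.mean()
    sd = ztr.std(ddof=0).replace(0.0, 1.0)
    return ((ztr - mean) / sd).to_numpy(), ((zte - mean) / sd).to_numpy()


def _pi_tables(
    basis: PiBasis, train: pd.DataFrame, test: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    return evaluate_pi(basis, train), evaluate_pi(basis, test)


def _score(report: EvaluationReport, reducer: str, family: str, split: str,
           y: np.ndarray, preds: list[np.ndarray], n_seeds: int) -> None:
    r2s = [r_squared(y, p) for p in preds]
    sms = [smape(y, p) for p in preds]
    rs = [pearson_r(y, p) for p in preds]
    for metric, vals in (("r2", r2s), ("smape", sms)):
        mean, sd = aggregate_seeds(vals)
        report.add(reducer, family, split, metric, mean, sd, n_seeds, len(y))
    mean_r, sd_r = aggregate_seeds([r for r, _ in rs])
    report.add(reducer, family, split, "pearson_r", mean_r, sd_r, n_seeds, len(y))
    mean_p, _ = aggregate_seeds([p for _, p in rs])
    report.add(reducer, family, split, "pearson_p", mean_p, None, n_seeds, len(y))


def run_comparison(
    table: pd.DataFrame,
    split: SplitSpec,
    config: ExperimentConfig | None = None,
    specs=None,
    repeating=None,
) -> tuple[EvaluationReport, dict]:
    """Run the full reducer x regressor benchmark on one observation table.

    Returns the tidy evaluation report plus a details dict (split sizes,
    NN traces per reducer, basis report).
    """
    config = config or ExperimentConfig()
    if specs is None:
        specs = dataio.biofilter_specs()
        if repeating is None:
            repeating = dataio.biofilter_repeating()
    symbols = [s.symbol for s in specs]
    indep_syms = [s.symbol for s in specs if s.role == "independent"]
    dep_sym = next(s.symbol for s in specs if s.role == "dependent")

    clean, dropped = dataio.drop_incomplete(table, symbols)
    train, test = dataio.split_by_study(clean, split)
    logger.info("split: %d train / %d test rows (%d dropped)", len(train), len(test), dropped)

    basis = construct_pi_basis(specs, repeating=repeating)
    pi_tr, pi_te = _pi_tables(basis, train, test)
    dep_label = basis.dependent.label

    y_tr = train[dep_sym].to_numpy(dtype=float)
    y_te = test[dep_sym].to_numpy(dtype=float)
    ic_tr = train["IC_org"].to_numpy(dtype=float)
    ic_te = test["IC_org"].to_numpy(dtype=float)

    raw_std = fit_standardizer(np.log(train[indep_syms]))
    raw_tr = apply_standardizer(raw_std, np.log(train[indep_syms])).to_numpy()
    raw_te = apply_standardizer(raw_std, np.log(test[indep_syms])).to_numpy()

    report = EvaluationReport()
    details: dict = {
        "n_train": len(train),
        "n_test": len(test),
        "n_dropped": dropped,
        "basis": basis.report(),
        "traces": {},
    }

    for reducer_name in config.reducers:
        feats = _feature_pathway(
            reducer_name, config, basis, pi_tr, pi_te, raw_tr, raw_te
        )
        for family in config.families:
            _run_family(
                report, details, reducer_name, family, config, feats,
                y_tr, y_te, ic_tr, ic_te, pi_tr, pi_te, dep_label,
            )
    return report, details


def _feature_pathway(name, config, basis, pi_tr, pi_te, raw_tr, raw_te) -> dict:
    """Standardized model inputs for one reducer pathway.

    For stochastic reducers (autoencoder) a callable keyed by seed is
    returned so the NN family can refit the reducer per seed.
    """
    if name == "BP":
        labels = basis.labels
        std = fit_standardizer(np.log(pi_tr[labels]))
        return {
            "kind": "BP",
            "train": apply_standardizer(std, np.log(pi_tr[labels])).to_numpy(),
            "test": apply_standardizer(std, np.log(pi_te[labels])).to_numpy(),
        }
    if name in ("PCA", "KPCA"):
        red = (
            reducers.fit_pca(raw_tr, k=4)
            if name == "PCA"
            else reducers.fit_kpca(raw_tr, k=4)
        )
        ztr = pd.DataFrame(reducers.transform(red, raw_tr))
        zte = pd.DataFrame(reducers.transform(red, raw_te))
        strain, stest = _standardize_reduced(ztr, zte)
        return {"kind": name, "train": strain, "test": stest}
    if name == "Autoencoder":
        cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}

        def per_seed(seed: int) -> tuple[np.ndarray, np.ndarray]:
            if seed not in cache:
                red = reducers.fit_autoencoder(
                    raw_tr, bottleneck=4, seed=seed, max_epochs=config.ae_max_epochs
                )
                ztr = pd.DataFrame(reducers.transform(red, raw_tr))
                zte = pd.DataFrame(reducers.transform(red, raw_te))
                cache[seed] = _standardize_reduced(ztr, zte)
            return cache[seed]

        ztr0, zte0 = per_seed(0)
        return {"kind": name, "train": ztr0, "test": zte0, "per_seed": per_seed}
    raise ValueError(f"unknown reducer {name!r}")


def _run_family(
    report, details, reducer_name, family, config, feats,
    y_tr, y_te, ic_tr, ic_te, pi_tr, pi_te, dep_label,
) -> None:
    is_bp = feats["kind"] == "BP"
    # BP models learn the log dimensionless ratio and are exponentiated and
    # back-transformed; data-driven pathways learn log effluent carbon.
    t_tr = np.log(pi_tr[dep_label].to_numpy() if is_bp else y_tr)
    if is_bp:
        to_ec_tr = lambda p: models.back_transform(np.exp(p), ic_tr)
        to_ec_te = lambda p: models.back_transform(np.exp(p), ic_te)
    else:
        to_ec_tr = to_ec_te = np.exp

    if family == "NN":
        preds_tr, preds_te = [], []
        for seed in config.ffnn.seeds:
            if "per_seed" in feats:
                xtr, xte = feats["per_seed"](seed)
            else:
                xtr, xte = feats["train"], feats["test"]
            one = replace(config.ffnn, seeds=(seed,))
            res = models.train_ffnn(xtr, t_tr, one)
            if seed not in res.models:
                logger.warning("seed %d failed: %s", seed, res.failures)
                continue
            preds_tr.append(to_ec_tr(res.predict(xtr, seed)))
            preds_te.append(to_ec_te(res.predict(xte, seed)))
            details["traces"].setdefault(reducer_name, []).append(res.traces)
        if not preds_tr:
            return
        n = len(preds_tr)
        _score(report, reducer_name, "NN", "train", y_tr, preds_tr, n)
        _score(report, reducer_name, "NN", "test", y_te, preds_te, n)
        return

    if family == "LR":
        if is_bp:
            labels = [c for c in pi_tr.columns if c != dep_label]
            mono = models.fit_monomial(pi_tr[labels], pi_tr[dep_label])
            # predict_monomial is already on the linear ratio scale
            p_tr = models.back_transform(models.predict_monomial(mono, pi_tr[labels]), ic_tr)
            p_te = models.back_transform(models.predict_monomial(mono, pi_te[labels]), ic_te)
            details["monomial"] = mono
        else:
            ridge = models.train_ensemble(
                feats["train"], t_tr, EnsembleConfig(kind="ridge")
            )
            p_tr = to_ec_tr(ridge.predict(feats["train"]))
            p_te = to_ec_te(ridge.predict(feats["test"]))
        _score(report, reducer_name, "LR", "train", y_tr, [p_tr], 1)
        _score(report, reducer_name, "LR", "test", y_te, [p_te], 1)
        return

    kind = _ENSEMBLE_KINDS.get(family)
    if kind is None:
        raise ValueError(f"unknown model family {family!r}")
    est = models.train_ensemble(feats["train"], t_tr, EnsembleConfig(kind=kind))
    p_tr = to_ec_tr(est.predict(feats["train"]))
    p_te = to_ec_te(est.predict(feats["test"]))
    _score(report, reducer_name, family, "train", y_tr, [p_tr], 1)
    _score(report, reducer_name, family, "test", y_te, [p_te], 1)


# ---------------------------------------------------------------------------
# focused experiments
# ---------------------------------------------------------------------------


def _two_scale_tables(
    seed: int, n_train: int, n_test: int, sigma: float
) -> pd.DataFrame:
    """Two geometrically similar 'studies' whose length scales differ 10x.

    The second study multiplies pore size, particle diameter and bed
    diameter by 10 (a full-scale filter geometrically similar to the lab
    columns), so the pi-groups are identically distributed across studies
    while the raw variables shift by an order of magnitude.
    """
    base = dict(synthetic.DEFAULT_RANGES)
    base["C_fit"] = (2.0e-2, 2.0e-1)
    cfg1 = synthetic.SyntheticConfig(
        n_rows=n_train, ranges=base, sigma=sigma, n_studies=1,
        study_sizes=None, seed=seed,
    )
    scaled = dict(base)
    for sym in ("Pz", "P", "C_fit"):
        lo, hi = scaled[sym]
        scaled[sym] = (10 * lo, 10 * hi)
    cfg2 = synthetic.SyntheticConfig(
        n_rows=n_test, ranges=scaled, sigma=sigma, n_studies=1,
        study_sizes=None, seed=seed + 1,
    )
    t1 = synthetic.generate(cfg1)
    t2 = synthetic.generate(cfg2)
    t1["study_id"] = "lab"
    t2["study_id"] = "full_scale"
    return pd.concat([t1, t2], ignore_index=True)


def ablation_experiment(
    seed: int = 0,
    n_train: int = 200,
    n_test: int = 60,
    sigma: float = 0.02,
    ffnn: FFNNConfig | None = None,
) -> dict:
    """Same network, pi features vs raw variables, across a 10x scale gap.

    Trains on the lab-scale study and tests on the full-scale study.  The
    pi pathway predicts the dimensionless ratio (back-transformed before
    scoring); the raw pathway predicts effluent carbon directly from the
    standardized dimensional variables.  Returns mean test R^2 for both.
    """
    ffnn = ffnn or FFNNConfig()
    table = _two_scale_tables(seed, n_train, n_test, sigma)
    specs = dataio.biofilter_specs()
    indep_syms = [s.symbol for s in specs if s.role == "independent"]
    train, test = dataio.split_by_study(
        table, SplitSpec(holdout_study="full_scale", train_quota=0, seed=seed)
    )
    basis = construct_pi_basis(specs, repeating=dataio.biofilter_repeating())
    pi_tr, pi_te = _pi_tables(basis, train, test)
    dep_label = basis.dependent.label
    labels = basis.labels

    y_te = test["EC_org"].to_numpy(dtype=float)
    ic_te = test["IC_org"].to_numpy(dtype=float)

    std_pi = fit_standardizer(np.log(pi_tr[labels]))
    z_tr = apply_standardizer(std_pi, np.log(pi_tr[labels])).to_numpy()
    z_te = apply_standardizer(std_pi, np.log(pi_te[labels])).to_numpy()
    std_raw = fit_standardizer(np.log(train[indep_syms]))
    x_tr = apply_standardizer(std_raw, np.log(train[indep_syms])).to_numpy()
    x_te = apply_standardizer(std_raw, np.log(test[indep_syms])).to_numpy()

    r2_pi, r2_raw = [], []
    for s in ffnn.seeds:
        one = replace(ffnn, seeds=(s,))
        res_pi = models.train_ffnn(z_tr, np.log(pi_tr[dep_label].to_numpy()), one)
        res_raw = models.train_ffnn(x_tr, np.log(train["EC_org"].to_numpy()), one)
        if s in res_pi.models:
            pred = models.back_transform(np.exp(res_pi.predict(z_te, s)), ic_te)
            r2_pi.append(r_squared(y_te, pred))
        if s in res_raw.models:
            r2_raw.append(r_squared(y_te, np.exp(res_raw.predict(x_te, s))))
    return {
        "r2_pi": aggregate_seeds(r2_pi)[0],
        "r2_raw": aggregate_seeds(r2_raw)[0],
        "n_train": n_train,
        "n_test": n_test,
    }


def structural_surrogate(
    seed: int = 0,
    n_train: int = 250,
    n_test: int = 60,
    sigma: float = 0.02,
    ffnn: FFNNConfig | None = None,
) -> dict:
    """Physics-pathway network on monomial-law synthetic data.

    Generates a two-study table (train study + held-out study), trains
    the network on standardized pi features over all configured seeds,
    and reports mean/SD test R^2 and sMAPE on the dimensional effluent
    concentration, plus the monomial model's test R^2 for reference.
    """
    ffnn = ffnn or FFNNConfig()
    cfg = synthetic.SyntheticConfig(
        n_rows=n_train + n_test,
        sigma=sigma,
        n_studies=2,
        study_sizes=(n_train, n_test),
        seed=seed,
    )
    table = synthetic.generate(cfg)
    split = SplitSpec(holdout_study="study_2", train_quota=0, seed=seed)
    config = ExperimentConfig(reducers=("BP",), families=("NN", "LR"), ffnn=ffnn)
    report, details = run_comparison(table, split, config)
    frame = report.to_frame()

    def pick(family, split_, metric):
        m = frame[
            (frame.family == family) & (frame.split == split_) & (frame.metric == metric)
        ]
        row = m.iloc[0]
        sd = row["sd"]
        return float(row["value"]), (None if pd.isna(sd) else float(sd))

    r2_mean, r2_sd = pick("NN", "test", "r2")
    sm_mean, sm_sd = pick("NN", "test", "smape")
    return {
        "nn_test_r2_mean": r2_mean,
        "nn_test_r2_sd": r2_sd,
        "nn_test_smape_mean": sm_mean,
        "nn_test_smape_sd": sm_sd,
        "lr_test_r2": pick("LR", "test", "r2")[0],
        "n_train": details["n_train"],
        "n_test": details["n_test"],
    }


def monomial_recovery(
    n: int = 300,
    sigma: float = 0.05,
    replicates: int = 100,
    tol=0.05,
    seed: int = 0,
) -> dict:
    """Seeded replicate study of monomial exponent recovery.

    For each replicate, generates ``n`` observations under the default
    monomial law with log-noise ``sigma``, fits the power-law model on
    the pi features, and checks each recovered exponent against truth.
    ``tol`` may be a scalar or one tolerance per exponent.  Returns
    per-exponent within-tolerance rates and the worst absolute errors.
    """
    truth = np.asarray(synthetic.DEFAULT_BETA)
    specs = dataio.biofilter_specs()
    basis = construct_pi_basis(specs, repeating=dataio.biofilter_repeating())
    labels = basis.labels
    dep_label = basis.dependent.label
    errors = np.empty((replicates, truth.size))
    b0_err = np.empty(replicates)
    for k in range(replicates):
        cfg = synthetic.SyntheticConfig(
            n_rows=n, sigma=sigma, study_sizes=None, seed=seed * 1000 + k
        )
        table = synthetic.generate(cfg)
        pi = evaluate_pi(basis, table)
        model = models.fit_monomial(pi[labels], pi[dep_label])
        est = np.array([model.exponents[c] for c in labels])
        errors[k] = np.abs(est - truth)
        b0_err[k] = abs(model.beta0 - synthetic.DEFAULT_BETA0)
    tol_vec = np.broadcast_to(np.asarray(tol, dtype=float), truth.shape)
    within = errors <= tol_vec
    return {
        "per_exponent_rate": within.mean(axis=0).tolist(),
        "all_within_rate": float(within.all(axis=1).mean()),
        "max_abs_error": float(errors.max()),
        "per_exponent_max_abs_error": errors.max(axis=0).tolist(),
        "beta0_max_abs_error": float(b0_err.max()),
        "n": n,
        "replicates": replicates,
        "tol": tol_vec.tolist(),
        "sigma": sigma,
    }
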