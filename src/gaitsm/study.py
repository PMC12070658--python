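"""End-to-end study orchestration.

`GaitQualityStudy` is the model object: built from a cohort of trial
recordings (able-bodied controls forming the normative reference plus
prosthetic-user patients), its :meth:`~GaitQualityStudy.fit` runs the full
design — cycle segmentation and sampling, normative-model construction,
all gait-quality measures, and the cohort statistics — and returns a
:class:`StudyResults` carrying the score table, the BH-adjusted Spearman
correlation family and the subgroup Welch tests, with a ``summary()`` table.

Score columns (12 by default): GPS, HMM-SM/MDP/DTW for each sensor
configuration, INI and MGS.  Higher HMM-SM means closer to normative gait;
every other score grows with deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import baselines, gps as _gps, hmm as _hmm, parameters as _par, stats as _stats
from .io import (
    GaitCycleSet,
    SENSOR_CONFIGURATIONS,
    TrialRecording,
    build_normative_set,
    resolve_side,
    sample_cycles,
    segment_cycles,
)

__all__ = ["StudyConfig", "NormativeModel", "GaitQualityStudy", "StudyResults", "run_pipeline"]


@dataclass
class StudyConfig:
    """All knobs of the study design, with the published defaults."""

    working_rate: float = 40.0
    n_cycles_patient: int = 100
    n_cycles_control: int = 10
    configs: tuple[str, ...] = ("pelvis", "upper_legs", "lower_legs")
    side: str = "prosthetic"
    # HMM-SM
    n_states: int = 5
    window: int = 10
    stride: int = 1
    n_restarts: int = 5
    n_iter: int = 200
    tol: float = 1e-4
    # kernel scale: None = self-calibrate from the control model (recommended)
    tau: float | None = None
    # MDP
    som_grid: tuple[int, int] = (10, 10)
    som_epochs: int = 50
    # parameter measures
    mgs_config: str = "lower_legs"
    # statistics
    fdr_q: float = 0.05
    alpha: float = 0.05
    seed: int = 0

    def fit_kwargs(self) -> dict:
        return dict(
            n_states=self.n_states,
            n_restarts=self.n_restarts,
            n_iter=self.n_iter,
            tol=self.tol,
        )


@dataclass
class NormativeModel:
    """Everything derived from the able-bodied reference set."""

    cycles: dict[str, GaitCycleSet]  # per sensor configuration
    channel_mean: dict[str, np.ndarray]
    channel_std: dict[str, np.ndarray]
    control_hmm: dict[str, _hmm.GaussianHMM]
    tau: dict[str, float]
    som: dict[str, baselines.SOMCodebook]
    control_mean_kinematics: _gps.KinematicCycle | None
    ini_basis: _par.PCABasis | None
    mgs_normative: pd.DataFrame | None  # per-control MGS parameter rows
    control_subsets: dict[str, GaitCycleSet] = field(default_factory=dict)

    def z_cycles(self, cycles: GaitCycleSet, config: str) -> GaitCycleSet:
        """Cycle set z-normalized by this model's channel statistics."""
        m, s = self.channel_mean[config], self.channel_std[config]
        return GaitCycleSet(
            cycles=[_hmm.zscore_block(c, m, s) for c in cycles.cycles],
            channel_labels=list(cycles.channel_labels),
            participant_id=cycles.participant_id,
            rate=cycles.rate,
            meta=list(cycles.meta),
        )


def build_normative_model(
    controls: list[TrialRecording], config: StudyConfig, seed: int
) -> NormativeModel:
    """Segment, sample and aggregate the control cycles; fit lambda_control,
    the SOM codebook, the GPS control mean, the INI PCA basis and the MGS
    normative parameter rows."""
    root = np.random.SeedSequence(seed)
    s_norm, s_hmm, s_som = (int(c.generate_state(1)[0] % 2**31) for c in root.spawn(3))
    by_id = {r.participant_id: r for r in controls}

    cycles_cfg: dict[str, GaitCycleSet] = {}
    mean_cfg: dict[str, np.ndarray] = {}
    std_cfg: dict[str, np.ndarray] = {}
    hmm_cfg: dict[str, _hmm.GaussianHMM] = {}
    tau_cfg: dict[str, float] = {}
    som_cfg: dict[str, baselines.SOMCodebook] = {}
    subsets: dict[str, GaitCycleSet] = {}
    mgs_ref = (
        config.mgs_config if config.mgs_config in config.configs else config.configs[0]
    )
    for name in config.configs:
        cfg = SENSOR_CONFIGURATIONS[name]
        per_control = [
            segment_cycles(r, config.side, cfg, to_rate=config.working_rate)
            for r in controls
        ]
        agg = build_normative_set(per_control, n_per=config.n_cycles_control, seed=s_norm)
        m, s = _hmm.channel_stats(agg)
        cycles_cfg[name], mean_cfg[name], std_cfg[name] = agg, m, s
        z = [_hmm.zscore_block(c, m, s) for c in agg.cycles]
        seqs = _hmm.make_training_windows(z, window=config.window, stride=config.stride)
        hmm_cfg[name] = _hmm.fit_hmm(seqs, seed=s_hmm, **config.fit_kwargs())
        tau_cfg[name] = (
            config.tau if config.tau is not None else _hmm.calibrate_tau(hmm_cfg[name])
        )
        frames = np.concatenate([c.T for c in z], axis=0)
        som_cfg[name] = baselines.fit_som(
            frames, grid=config.som_grid, n_epochs=config.som_epochs, seed=s_som
        )
        if name == mgs_ref:
            # per-control sampled subsets, for the MGS normative rows
            for cid in by_id:
                idx = [
                    i for i, md in enumerate(agg.meta) if md.get("source") == cid
                ]
                sub = agg.subset(idx)
                sub.participant_id = cid
                subsets[cid] = sub

    agg = cycles_cfg[mgs_ref]

    # GPS control mean over the sampled normative cycles
    kin_cycles = []
    ini_tables = []
    mgs_rows = {}
    for cid, rec in by_id.items():
        pairs = [
            (md["start"], md["end"]) for md in agg.meta if md.get("source") == cid
        ]
        side = resolve_side(rec, config.side)
        kin_cycles.extend(_gps.extract_kinematic_cycles(rec, pairs, side))
        ini_tables.append(_par.ini_parameter_table(rec, pairs, side))
        if cid in subsets:
            mgs_rows[cid] = _par.mgs_parameters(rec, subsets[cid])
    control_mean = _gps.control_mean_cycle(kin_cycles)
    ini_basis = _par.fit_pca_basis(pd.concat(ini_tables, ignore_index=True))
    mgs_normative = pd.DataFrame(mgs_rows).T if mgs_rows else None

    return NormativeModel(
        cycles=cycles_cfg,
        channel_mean=mean_cfg,
        channel_std=std_cfg,
        control_hmm=hmm_cfg,
        tau=tau_cfg,
        som=som_cfg,
        control_mean_kinematics=control_mean,
        ini_basis=ini_basis,
        mgs_normative=mgs_normative,
        control_subsets=subsets,
    )


@dataclass
class StudyResults:
    """Fitted study: scores, correlation family, subgroup tests, provenance."""

    scores: pd.DataFrame  # index participants; 'group' + score columns
    correlations: pd.DataFrame
    subgroup_tests: pd.DataFrame
    normative: NormativeModel
    config: StudyConfig
    log: list[dict] = field(default_factory=list)

    @property
    def score_columns(self) -> list[str]:
        return [c for c in self.scores.columns if c != "group"]

    def summary(self) -> str:
        lines = [
            "Gait-quality study summary",
            "=" * 60,
            f"participants scored : {len(self.scores)}",
            f"score columns       : {len(self.score_columns)}",
            f"sensor configs      : {', '.join(self.config.configs)}",
            "",
            "Spearman correlations with GPS (BH-adjusted p):",
        ]
        gps_rows = self.correlations[
            (self.correlations.measure_a == "GPS") | (self.correlations.measure_b == "GPS")
        ]
        for _, row in gps_rows.iterrows():
            other = row.measure_b if row.measure_a == "GPS" else row.measure_a
            star = " *" if row.significant else ""
            lines.append(f"  {other:<22s} r = {row.r:+.3f}  p_adj = {row.p_adj:.3f}{star}")
        sig = self.subgroup_tests[self.subgroup_tests.significant]
        lines += ["", f"significant subgroup differences (Welch, alpha = "
                      f"{self.config.alpha:g}): {len(sig)}"]
        for _, row in sig.iterrows():
            lines.append(
                f"  {row.measure:<22s} {row.group_a}-{row.group_b}  p = {row.p:.4f}"
            )
        if self.log:
            lines += ["", f"stage failures recorded: {len(self.log)}"]
        return "\n".join(lines)


class GaitQualityStudy:
    """Model object over a cohort of trial recordings.

    Controls (group ``AB``) form the normative reference; every other
    recording is a patient to be scored.  ``fit()`` returns
    :class:`StudyResults`.
    """

    def __init__(self, recordings: list[TrialRecording], config: StudyConfig | None = None):
        self.config = config or StudyConfig()
        self.controls = [r for r in recordings if r.group == "AB"]
        self.patients = [r for r in recordings if r.group != "AB"]
        if not self.controls:
            raise ValueError("cohort has no able-bodied (AB) controls")

    @classmethod
    def from_synthetic(cls, spec=None, config: StudyConfig | None = None) -> "GaitQualityStudy":
        from .synthetic import CohortSpec, generate_cohort

        spec = spec or CohortSpec(seed=(config.seed if config else 0))
        return cls(generate_cohort(spec), config=config)

    def fit(self) -> StudyResults:
        cfg = self.config
        root = np.random.SeedSequence(cfg.seed)
        s_normative = int(root.spawn(1)[0].generate_state(1)[0] % 2**31)
        normative = build_normative_model(self.controls, cfg, s_normative)
        log: list[dict] = []
        rows = {}
        mgs_param_rows = {}
        scored = self.patients + self.controls  # controls get resubstitution scores
        children = np.random.SeedSequence((cfg.seed, 1)).spawn(len(scored))
        for rec, child in zip(scored, children):
            seeds = child.generate_state(2) % 2**31
            row: dict[str, float] = {"group": rec.group}
            sampled: dict[str, GaitCycleSet] = {}
            for name in cfg.configs:
                try:
                    cs = segment_cycles(
                        rec, cfg.side, SENSOR_CONFIGURATIONS[name], to_rate=cfg.working_rate
                    )
                    n = min(cfg.n_cycles_patient, cs.n_cycles)
                    sampled[name] = sample_cycles(cs, n, int(seeds[0]))
                except Exception as err:  # participant fails this stage, not the study
                    log.append({"participant": rec.participant_id, "stage": f"segment:{name}",
                                "error": str(err)})
            for name, cs in sampled.items():
                zc = normative.z_cycles(cs, name)
                znorm = normative.z_cycles(normative.cycles[name], name)
                try:
                    row[f"HMM-SM_{name}"] = _hmm.hmm_sm_participant(
                        zc,
                        normative.control_hmm[name],
                        config_name=name,
                        window=cfg.window,
                        stride=cfg.stride,
                        seed=int(seeds[1]),
                        tau=normative.tau[name],
                        **cfg.fit_kwargs(),
                    ).S
                except Exception as err:
                    log.append({"participant": rec.participant_id, "stage": f"hmmsm:{name}",
                                "error": str(err)})
                    row[f"HMM-SM_{name}"] = np.nan
                try:
                    row[f"MDP_{name}"] = baselines.mdp_participant(zc, normative.som[name])
                except Exception as err:
                    log.append({"participant": rec.participant_id, "stage": f"mdp:{name}",
                                "error": str(err)})
                    row[f"MDP_{name}"] = np.nan
                try:
                    row[f"DTW_{name}"] = baselines.dtw_score(zc, znorm)
                except Exception as err:
                    log.append({"participant": rec.participant_id, "stage": f"dtw:{name}",
                                "error": str(err)})
                    row[f"DTW_{name}"] = np.nan
            if cfg.mgs_config in sampled:
                ref = cfg.mgs_config
            else:
                ref = next(iter(sampled), None)
            pairs = (
                [(md["start"], md["end"]) for md in sampled[ref].meta] if ref else None
            )
            try:
                side = resolve_side(rec, cfg.side)
                kin = _gps.extract_kinematic_cycles(rec, pairs, side)
                row["GPS"] = _gps.gps_participant(kin, normative.control_mean_kinematics)
            except Exception as err:
                log.append({"participant": rec.participant_id, "stage": "gps",
                            "error": str(err)})
                row["GPS"] = np.nan
            try:
                table = _par.ini_parameter_table(rec, pairs, cfg.side)
                row["INI"] = _par.ini_score(table, normative.ini_basis)
            except Exception as err:
                log.append({"participant": rec.participant_id, "stage": "ini",
                            "error": str(err)})
                row["INI"] = np.nan
            if ref:
                try:
                    mgs_param_rows[rec.participant_id] = _par.mgs_parameters(
                        rec, sampled[ref]
                    )
                except Exception as err:
                    log.append({"participant": rec.participant_id, "stage": "mgs",
                                "error": str(err)})
            rows[rec.participant_id] = row
        scores = pd.DataFrame(rows).T
        scores.index.name = "participant_id"

        # MGS scored jointly against the control parameter rows; the normative
        # rows get a prefix so scored controls don't collide with them
        if mgs_param_rows and normative.mgs_normative is not None:
            norm_tab = normative.mgs_normative.copy()
            norm_tab.index = [f"norm::{i}" for i in norm_tab.index]
            table = pd.concat([norm_tab, pd.DataFrame(mgs_param_rows).T])
            overall, _, _ = _par.mgs_score(
                table, normative_rows=list(norm_tab.index)
            )
            scores["MGS"] = overall.reindex(scores.index)

        ordered = ["group", "GPS"]
        for m in ("HMM-SM", "MDP", "DTW"):
            ordered += [f"{m}_{c}" for c in cfg.configs if f"{m}_{c}" in scores.columns]
        ordered += [c for c in ("INI", "MGS") if c in scores.columns]
        scores = scores[ordered]
        score_cols = [c for c in ordered if c != "group"]
        scores[score_cols] = scores[score_cols].astype(float)

        # statistics follow the study design: computed across the patients
        patients = scores[scores.group != "AB"]
        usable = [c for c in score_cols if patients[c].notna().sum() >= 4]
        dropped = sorted(set(score_cols) - set(usable))
        if dropped:
            log.append({"participant": None, "stage": "correlations",
                        "error": f"columns with <4 observations excluded: {dropped}"})
        correlations = _stats.correlation_table(
            patients[usable], q=cfg.fdr_q, alpha=cfg.alpha
        )
        sub_rows = []
        groups = tuple(g for g in ("TT", "TF", "VN", "LS") if (scores.group == g).sum() >= 2)
        for m in score_cols:
            n_ok = sum(
                scores.loc[scores.group == g, m].notna().sum() >= 2 for g in groups
            )
            if n_ok < 2:
                continue
            res = _stats.group_difference_tests(
                scores, m, groups=groups, alpha=cfg.alpha
            )
            for pw in res["pairwise"]:
                sub_rows.append(
                    {
                        "measure": m,
                        "group_a": pw.groups[0],
                        "group_b": pw.groups[1],
                        "t": pw.t,
                        "df": pw.df,
                        "p": pw.p,
                        "significant": pw.significant,
                        "omnibus_p": res["omnibus"]["p"],
                    }
                )
        subgroup_tests = pd.DataFrame(
            sub_rows,
            columns=["measure", "group_a", "group_b", "t", "df", "p", "significant",
                     "omnibus_p"],
        )
        return StudyResults(
            scores=scores,
            correlations=correlations,
            subgroup_tests=subgroup_tests,
            normative=normative,
            config=cfg,
            log=log,
        )


def run_pipeline(
    recordings: list[TrialRecording], config: StudyConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Functional wrapper: (score table, correlation table, subgroup table)."""
    res = GaitQualityStudy(recordings, config=config).fit()
    return res.scores, res.correlations, res.subgroup_tests
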