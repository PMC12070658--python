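"""Scaled-down synthetic study and deviation sweeps.

These runners exercise the full study design on the synthetic world at a
size that fits a single CPU: a reduced cohort, one sensor configuration
(the lower legs, the best-performing location), a sliding-window stride of
5 instead of 1 and a reduced EM budget.  They back the package's own
validation; the thresholds they are checked against live in the test suite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import hmm as _hmm
from .baselines import dtw_score, mdp_participant
from .gps import extract_kinematic_cycles, gps_participant
from .io import SENSOR_CONFIGURATIONS, sample_cycles, segment_cycles
from .parameters import ini_parameter_table, ini_score
from .study import GaitQualityStudy, StudyConfig, StudyResults, build_normative_model
from .synthetic import SubjectProfile, deviation_grid_cohort, generate_subject

__all__ = ["scaled_study_config", "run_scaled_study", "deviation_sweep"]


def scaled_study_config(seed: int = 0) -> StudyConfig:
    """Reduced-cost study configuration for the scaled synthetic study."""
    return StudyConfig(
        configs=("lower_legs",),
        n_cycles_patient=50,
        n_cycles_control=10,
        window=10,
        stride=5,
        n_restarts=2,
        n_iter=100,
        som_epochs=30,
        seed=seed,
    )


def run_scaled_study(seed: int = 0) -> StudyResults:
    """The full study design at reduced size: 10 controls (10 cycles each in
    the normative set), 16 patients (50 sampled cycles) with severities on an
    even grid over [0, 1]."""
    recs = deviation_grid_cohort(
        n_control=10, n_patient=16, cycles_control=14, cycles_patient=50, seed=seed
    )
    return GaitQualityStudy(recs, config=scaled_study_config(seed)).fit()


def deviation_sweep(
    seed: int = 0,
    levels: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0),
    n_seeds: int = 5,
    n_cycles: int = 20,
    config: StudyConfig | None = None,
) -> pd.DataFrame:
    """Median score of every measure per deviation level over seeded subjects.

    One normative model (10 controls) is built once; ``n_seeds`` fresh
    subjects are generated and scored at each severity level.  Returns a
    tidy frame (level, seed, measure columns).
    """
    cfg = config or scaled_study_config(seed)
    cfg_name = cfg.configs[0]
    sensor_cfg = SENSOR_CONFIGURATIONS[cfg_name]
    root = np.random.SeedSequence((seed, 99))
    controls = deviation_grid_cohort(
        n_control=10, n_patient=0, cycles_control=14, seed=seed
    )
    normative = build_normative_model(
        controls, cfg, int(root.spawn(1)[0].generate_state(1)[0] % 2**31)
    )
    lam_c = normative.control_hmm[cfg_name]
    tau = normative.tau[cfg_name]
    znorm = normative.z_cycles(normative.cycles[cfg_name], cfg_name)
    rows = []
    children = root.spawn(len(levels) * n_seeds)
    k = 0
    for d in levels:
        for rep in range(n_seeds):
            seeds = children[k].generate_state(3) % (2**31)
            k += 1
            prof = SubjectProfile.draw(
                f"D{d:.2f}R{rep}", "TT", d, int(seeds[0]), "left"
            )
            rec = generate_subject(prof, n_cycles + 5, int(seeds[1]), n_passes=2)
            cs = segment_cycles(rec, cfg.side, sensor_cfg, to_rate=cfg.working_rate)
            cs = sample_cycles(cs, n_cycles, int(seeds[2]))
            zc = normative.z_cycles(cs, cfg_name)
            pairs = [(md["start"], md["end"]) for md in cs.meta]
            row = {"level": d, "rep": rep}
            row["HMM-SM"] = _hmm.hmm_sm_participant(
                zc, lam_c, window=cfg.window, stride=cfg.stride,
                seed=int(seeds[2]), tau=tau, **cfg.fit_kwargs(),
            ).S
            row["MDP"] = mdp_participant(zc, normative.som[cfg_name])
            row["DTW"] = dtw_score(zc, znorm)
            kin = extract_kinematic_cycles(rec, pairs, "left")
            row["GPS"] = gps_participant(kin, normative.control_mean_kinematics)
            row["INI"] = ini_score(
                ini_parameter_table(rec, pairs, "left"), normative.ini_basis
            )
            rows.append(row)
    return pd.DataFrame(rows)
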