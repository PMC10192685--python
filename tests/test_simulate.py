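"""Synthetic plate generator: determinism, calibration, signal recovery."""

import numpy as np
import pytest

from aimeshift.errors import PlateConfigError
from aimeshift.fitting import FitConfig
from aimeshift.normalize import baseline_responses, compute_bmad_cutoff, normalize
from aimeshift.pipeline import analyze_experiment, extract_series
from aimeshift.plates import frame_to_wells
from aimeshift.shift import ExpectedClass
from aimeshift.simulate import (
    ChemicalTruth,
    SyntheticTruth,
    default_truth,
    generate_experiment,
    generate_null_plates,
)


def _single_chem_truth(mult, seed=0, noise_sd=0.1, tp=2.0):
    cls = (ExpectedClass.BIOACTIVATED if mult > 1
           else ExpectedClass.BIOINACTIVATED if mult < 1 else None)
    return SyntheticTruth(
        chemicals={"chem": ChemicalTruth(
            "hill", {"tp": tp, "ga": 10.0, "p": 1.5}, tp_multiplier=mult,
            expected_class=cls)},
        noise_sd=noise_sd, seed=seed,
    )


class TestDeterminism:
    def test_same_seed_identical_tables(self):
        t = default_truth(4, seed=42)
        w1, _ = generate_experiment(t, 2)
        w2, _ = generate_experiment(t, 2)
        assert w1.equals(w2)

    def test_different_seed_differs(self):
        w1, _ = generate_experiment(default_truth(4, seed=1), 1)
        w2, _ = generate_experiment(default_truth(4, seed=2), 1)
        assert not w1["raw_lum"].equals(w2["raw_lum"])


class TestNullEffect:
    def test_zero_noise_identity_multiplier_modes_identical(self):
        truth = SyntheticTruth(
            chemicals={"chem": ChemicalTruth("hill", {"tp": 2.0, "ga": 10.0, "p": 1.5})},
            noise_sd=0.0, dropout_rate=0.0, seed=0,
        )
        wells, _ = generate_experiment(truth, 1)
        test = wells[wells["chemical_id"] == "chem"]
        neg = test[test["mode"] == "MetNeg"].sort_values("conc")["raw_lum"].to_numpy()
        pos = test[test["mode"] == "MetPos"].sort_values("conc")["raw_lum"].to_numpy()
        assert np.allclose(neg, pos)

    def test_zero_noise_null_fits_constant(self):
        truth = default_truth(2, seed=0, noise_sd=0.0)
        truth = SyntheticTruth(chemicals=truth.chemicals, noise_sd=0.0,
                               dropout_rate=0.0, seed=0)
        nulls = generate_null_plates(truth, 4)
        norm = normalize(frame_to_wells(nulls))
        base = compute_bmad_cutoff(baseline_responses(norm))
        assert base.bmad == 0.0
        from aimeshift.fitting import fit_series

        for s in extract_series(norm):
            res = fit_series(s, base, FitConfig(seed=0))
            assert res.winner.model_name == "constant"
            assert res.hitc == 0.0


class TestCalibration:
    def test_bmad_matches_lognormal_closed_form(self):
        # baseline resp = e^eps - 1 with eps ~ N(0, sigma), whose MAD is
        # ~0.6745*sigma for small sigma; a single batch has ~5% sampling
        # spread, so the moment check is on the mean over batches
        sigma = 0.1
        bmads = []
        for seed in range(8):
            truth = default_truth(2, seed=seed, noise_sd=sigma)
            nulls = generate_null_plates(truth, 8)
            norm = normalize(frame_to_wells(nulls))
            bmads.append(compute_bmad_cutoff(baseline_responses(norm)).bmad)
        assert np.mean(bmads) == pytest.approx(0.67448975 * sigma, rel=0.05)

    def test_bval_recovery_rms_within_2pct(self):
        # per-plate baseline median vs the generating plate scale; the
        # per-plate sampling sd at sigma=0.1 with ~62 DMSO wells is ~1.6%,
        # so the calibration check is on the RMS error over many plates
        truth = default_truth(3, seed=8)
        wells, _ = generate_experiment(truth, 30)
        records = frame_to_wells(wells)
        norm = normalize(records)
        rel_errs = []
        for pid, grp in norm.groupby("plate_id"):
            bval = grp["bval"].iloc[0]
            # recover the generating scale from the noiseless expectation:
            # DMSO raw = bval_true * e^eps, median e^eps ~ 1
            rep = int(pid.replace("plate", "")) - 1
            rng = np.random.default_rng([truth.seed, rep])
            scale = rng.uniform(*truth.plate_scale_range)
            rel_errs.append(bval / (truth.bval * scale) - 1.0)
        rms = float(np.sqrt(np.mean(np.square(rel_errs))))
        assert rms < 0.02

    def test_dropout_rate_bounds_enforced(self):
        with pytest.raises(PlateConfigError):
            SyntheticTruth(chemicals={}, dropout_rate=0.5)

    def test_directional_class_consistency_enforced(self):
        with pytest.raises(PlateConfigError):
            ChemicalTruth("hill", {"tp": 1.0, "ga": 10.0, "p": 1.0},
                          tp_multiplier=0.5,
                          expected_class=ExpectedClass.BIOACTIVATED)


class TestRecovery:
    def test_direction_recovered_for_doubling(self):
        truth = _single_chem_truth(2.0, seed=13)
        wells, _ = generate_experiment(truth, 4)
        res = analyze_experiment(
            wells, {"chem": ExpectedClass.BIOACTIVATED}, FitConfig(seed=13))
        (rec,) = res.shifts
        assert rec.direction == "activated"
        assert rec.concordant is True

    def test_direction_recovered_for_halving(self):
        truth = _single_chem_truth(0.5, seed=14)
        wells, _ = generate_experiment(truth, 4)
        res = analyze_experiment(
            wells, {"chem": ExpectedClass.BIOINACTIVATED}, FitConfig(seed=14))
        (rec,) = res.shifts
        assert rec.direction == "inactivated"
        assert rec.concordant is True

    def test_positive_call_power_monotone_in_tp(self):
        # fraction of positives should not decrease with the true top
        rates = []
        for tp in (0.15, 0.5, 2.0):
            pos = 0
            n = 12
            for rep in range(n):
                truth = _single_chem_truth(1.0, seed=100 + rep, tp=tp)
                wells, _ = generate_experiment(truth, 4)
                res = analyze_experiment(wells, cfg=FitConfig(seed=rep))
                (curve,) = [c for c in res.curves if c.mode == "MetNeg"]
                pos += curve.hit_class == "positive"
            rates.append(pos / n)
        assert rates[0] <= rates[1] <= rates[2]
        assert rates[2] == 1.0


class TestControlQC:
    def test_controls_in_assay_relevant_mode_meet_quality_band(self):
        # the agonist and bioinactivated controls are informative without
        # metabolism; the bioactivated control with metabolism
        truth = default_truth(2, seed=21)
        wells, _ = generate_experiment(truth, 4)
        norm = normalize(frame_to_wells(wells))
        from aimeshift.normalize import control_qc_table

        qc = control_qc_table(
            norm, ["17beta-estradiol", "ethylparaben", "trans-stilbene"]
        ).set_index(["compound", "metabolism"])
        relevant = [("17beta-estradiol", "MetNeg"), ("ethylparaben", "MetNeg"),
                    ("trans-stilbene", "MetPos")]
        for key in relevant:
            row = qc.loc[key]
            assert float(row["CV"]) < 20.0
            assert 0.2 < float(row["Z-factor"]) <= 1.0
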