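"""Signature building, cross-detector normalization, authentication decisions."""

import numpy as np
import pytest
from dataclasses import replace

from nqrauth import (
    BENZOCAINE,
    CoilSpec,
    FeatureVector,
    SignatureStore,
    authenticate_package,
    build_signature,
    builtin_calibrations,
    extract_features,
    normalize_amplitude,
    simulate_echo_train,
)
from nqrauth.errors import (
    DegenerateSpreadError,
    DomainError,
    IncompatibleDataError,
    InsufficientDataError,
)


def _measure(coil, pulse, slse_params, package, sigma, seeds, sample=BENZOCAINE):
    return [
        extract_features(
            simulate_echo_train(sample, package, coil, pulse, slse_params, sigma, seed=s)
        )
        for s in seeds
    ]


@pytest.fixture(scope="module")
def reference_signature(coil, pulse, slse_params, thin_paper, sigma_for_snr):
    feats = _measure(coil, pulse, slse_params, thin_paper, sigma_for_snr(50.0), range(60))
    return build_signature(feats, "benzocaine", "thin_paper", "detector_a")


class TestBuildSignature:
    def test_identical_vectors_rejected_as_degenerate(self):
        fv = FeatureVector(1.0, 5e-3, 2000.0, 2.408e6)
        with pytest.raises(DegenerateSpreadError):
            build_signature([fv, fv, fv], "benzocaine", "thin_paper", "d")

    def test_too_few_vectors(self):
        fv = FeatureVector(1.0, 5e-3, 2000.0, 2.408e6)
        with pytest.raises(InsufficientDataError):
            build_signature([fv, fv], "benzocaine", "thin_paper", "d")

    def test_mixed_api_rejected(self):
        fv = FeatureVector(1.0, 5e-3, 2000.0, 2.408e6)
        fvs = [fv, replace(fv, initial_amplitude=1.1), replace(fv, initial_amplitude=0.9)]
        with pytest.raises(IncompatibleDataError):
            build_signature(
                fvs, "benzocaine", "thin_paper", "d",
                api_names=["benzocaine", "nicotinamide", "benzocaine"],
            )

    def test_means_within_two_standard_errors_of_truth(
        self, coil, pulse, slse_params, thin_paper, sigma_for_snr, noiseless_train
    ):
        truth = extract_features(noiseless_train)
        feats = _measure(coil, pulse, slse_params, thin_paper, sigma_for_snr(20.0), range(500))
        sig = build_signature(feats, "benzocaine", "thin_paper", "d")
        for name in ("initial_amplitude", "t2_effective", "linewidth"):
            se = sig.feature_sds[name] / np.sqrt(sig.n_measurements)
            # allow small estimator bias on top of the Monte-Carlo standard error
            tol = 2 * se + 0.01 * abs(getattr(truth, name))
            assert abs(sig.feature_means[name] - getattr(truth, name)) <= tol


class TestNormalizeAmplitude:
    def test_equal_references_identity(self):
        fv = FeatureVector(1.0, 5e-3, 2000.0, 2.408e6)
        assert normalize_amplitude(fv, 2.0, 2.0) == fv

    def test_t2_and_linewidth_untouched(self):
        fv = FeatureVector(1.0, 5e-3, 2000.0, 2.408e6)
        out = normalize_amplitude(fv, 1.0, 3.0)
        assert out.initial_amplitude == 3.0
        assert (out.t2_effective, out.linewidth, out.peak_frequency) == (
            5e-3, 2000.0, 2.408e6,
        )

    def test_nonpositive_reference_rejected(self):
        fv = FeatureVector(1.0, 5e-3, 2000.0, 2.408e6)
        with pytest.raises(DomainError):
            normalize_amplitude(fv, 0.0, 1.0)

    def test_two_detectors_agree_after_normalization(
        self, pulse, slse_params, thin_paper, sigma_for_snr
    ):
        from scipy import stats

        det_a = CoilSpec()
        det_b = CoilSpec(outer_side=0.05, n_turns=9)
        sigma = sigma_for_snr(50.0)
        feats_a = _measure(det_a, pulse, slse_params, thin_paper, sigma, range(80))
        feats_b = _measure(det_b, pulse, slse_params, thin_paper, sigma, range(100, 180))
        amps_a = np.array([f.initial_amplitude for f in feats_a])
        amps_b = np.array([f.initial_amplitude for f in feats_b])
        assert abs(amps_a.mean() - amps_b.mean()) > 3 * amps_a.std()  # raw scales differ
        norm_b = amps_b * amps_a.mean() / amps_b.mean()
        # two-sample location test on normalized amplitudes at alpha = 0.01
        _, p = stats.ttest_ind(amps_a, norm_b, equal_var=False)
        assert p > 0.01


class TestAuthenticatePackage:
    def test_means_are_authentic_with_zero_z(self, reference_signature):
        measured = FeatureVector(
            reference_signature.feature_means["initial_amplitude"],
            reference_signature.feature_means["t2_effective"],
            reference_signature.feature_means["linewidth"],
            reference_signature.feature_means["peak_frequency"],
        )
        report = authenticate_package(measured, reference_signature)
        assert report.verdict == "authentic"
        assert all(z == pytest.approx(0.0) for z in report.z_scores.values())

    def test_five_sigma_amplitude_shift_flagged(self, reference_signature):
        sig = reference_signature
        measured = FeatureVector(
            sig.feature_means["initial_amplitude"] + 5 * sig.feature_sds["initial_amplitude"],
            sig.feature_means["t2_effective"],
            sig.feature_means["linewidth"],
            sig.feature_means["peak_frequency"],
        )
        report = authenticate_package(measured, sig)
        assert report.verdict == "discrepancy"
        assert report.offending_features == ("initial_amplitude",)

    def test_quantification_branch(self, reference_signature):
        model = builtin_calibrations()["thin_paper"]
        measured = FeatureVector(
            model.predict_amplitude(12.0),
            reference_signature.feature_means["t2_effective"],
            reference_signature.feature_means["linewidth"],
            reference_signature.feature_means["peak_frequency"],
        )
        report = authenticate_package(measured, reference_signature, calibration=model)
        assert report.estimated_quantity_g == pytest.approx(12.0, abs=1e-9)
        assert report.quantity_status == "ok"

    def test_decision_invariant_under_joint_rescaling(self, reference_signature):
        from dataclasses import replace as dc_replace

        sig = reference_signature
        measured = FeatureVector(
            sig.feature_means["initial_amplitude"] * 1.02,
            sig.feature_means["t2_effective"],
            sig.feature_means["linewidth"],
            sig.feature_means["peak_frequency"],
        )
        r1 = authenticate_package(measured, sig)
        alpha = 7.3
        scaled_sig = dc_replace(
            sig,
            feature_means={**sig.feature_means,
                           "initial_amplitude": sig.feature_means["initial_amplitude"] * alpha},
            feature_sds={**sig.feature_sds,
                         "initial_amplitude": sig.feature_sds["initial_amplitude"] * alpha},
            amplitude_reference=sig.amplitude_reference * alpha,
        )
        scaled_measured = replace(measured, initial_amplitude=measured.initial_amplitude * alpha)
        r2 = authenticate_package(scaled_measured, scaled_sig)
        assert r1.verdict == r2.verdict
        assert r1.z_scores["initial_amplitude"] == pytest.approx(
            r2.z_scores["initial_amplitude"], rel=1e-9
        )

    def test_adulteration_detected_through_amplitude(
        self, coil, pulse, slse_params, thin_paper, sigma_for_snr, reference_signature
    ):
        # halved quantity, same API: amplitude feature must drive the discrepancy
        adulterated = replace(BENZOCAINE, quantity=BENZOCAINE.quantity / 2)
        sigma = sigma_for_snr(50.0)
        flagged = 0
        n_trials = 100
        for seed in range(1000, 1000 + n_trials):
            fv = extract_features(
                simulate_echo_train(
                    adulterated, thin_paper, coil, pulse, slse_params, sigma, seed=seed
                )
            )
            report = authenticate_package(fv, reference_signature)
            if report.verdict == "discrepancy" and "initial_amplitude" in report.offending_features:
                flagged += 1
        assert flagged >= 0.95 * n_trials

    def test_false_alarm_rate_matches_k_sigma(
        self, coil, pulse, slse_params, thin_paper, sigma_for_snr, reference_signature
    ):
        # in-distribution measurements: per-feature 3-sigma gating keeps most authentic
        sigma = sigma_for_snr(50.0)
        verdicts = []
        for seed in range(2000, 2150):
            fv = extract_features(
                simulate_echo_train(
                    BENZOCAINE, thin_paper, coil, pulse, slse_params, sigma, seed=seed
                )
            )
            verdicts.append(authenticate_package(fv, reference_signature).verdict)
        rate = np.mean([v == "authentic" for v in verdicts])
        # 4 features at ~3 sigma each -> expected authentic rate ~ (1 - 0.0027)^4 ~ 0.989
        assert rate >= 0.95

    def test_mahalanobis_option(self, reference_signature):
        sig = reference_signature
        measured = FeatureVector(
            sig.feature_means["initial_amplitude"],
            sig.feature_means["t2_effective"],
            sig.feature_means["linewidth"],
            sig.feature_means["peak_frequency"],
        )
        report = authenticate_package(measured, sig, mahalanobis=True)
        assert report.verdict == "authentic"


class TestSignatureStore:
    def test_round_trip(self, tmp_path, reference_signature):
        store = SignatureStore(tmp_path)
        store.put(reference_signature)
        back = store.get("benzocaine", "thin_paper", "detector_a")
        assert back == reference_signature
        assert store.list() == ["benzocaine__thin_paper__detector_a"]
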