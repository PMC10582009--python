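import numpy as np
import pandas as pd
import pytest

from erosure.diversity import DiversityTrack
from erosure.indicators import (
    Status,
    annual_change,
    classify_delta_fst,
    classify_delta_h,
    classify_ne,
    fst_to_migrants,
)


class TestAnnualChange:
    def test_no_change(self):
        assert annual_change(0.3, 0.3, 10) == 0.0

    def test_loss(self):
        assert annual_change(0.30, 0.27, 40) == pytest.approx(-0.25)

    def test_gain(self):
        assert annual_change(0.1, 0.2, 100) == pytest.approx(1.0)

    def test_errors(self):
        with pytest.raises(ValueError):
            annual_change(0.0, 0.1, 10)
        with pytest.raises(ValueError):
            annual_change(0.1, 0.1, 0)


def _cohort(mean, n=8, spread=1e-4, seed=0):
    # symmetric offsets: the sample mean is exactly `mean`
    return mean + np.linspace(-1, 1, n) * spread


class TestClassifyDeltaH:
    def test_nonsignificant_change_acceptable(self):
        # overlapping noisy cohorts: a warning-band magnitude alone never flags
        r = classify_delta_h(_cohort(0.30, spread=0.2), _cohort(0.28, spread=0.2), 40)
        assert not r.significant
        assert r.status == Status.ACCEPTABLE

    @pytest.mark.parametrize(
        "annual_loss,expected",
        [
            (0.04, Status.ACCEPTABLE),
            (0.05, Status.ACCEPTABLE),  # boundary: <= 0.05 acceptable
            (0.2, Status.WARNING),
            (0.3, Status.WARNING),  # boundary: <= 0.3 warning
            (0.31, Status.ALARM),
            (0.4, Status.ALARM),
        ],
    )
    def test_band_boundaries(self, annual_loss, expected):
        years = 40
        m1 = 0.30
        m2 = m1 * (1 - annual_loss * years / 100)
        r = classify_delta_h(_cohort(m1), _cohort(m2, seed=3), years)
        assert r.significant
        assert r.status == expected

    def test_gain_is_acceptable(self):
        r = classify_delta_h(_cohort(0.3), _cohort(0.4, seed=4), 40)
        assert r.significant and r.status == Status.ACCEPTABLE

    def test_froh_direction(self):
        # an F_ROH increase is diversity loss under loss-when-increasing
        r = classify_delta_h(
            _cohort(0.10), _cohort(0.13, seed=5), 40, direction="loss-when-increasing"
        )
        assert r.status == Status.ALARM  # +0.75 %/yr

    def test_concordance_flag_present(self):
        r = classify_delta_h(_cohort(0.3), _cohort(0.2, seed=6), 40)
        assert r.concordant in (True, False)
        assert r.p_wilcoxon is not None

    def test_bad_direction_errors(self):
        with pytest.raises(ValueError, match="direction"):
            classify_delta_h(_cohort(0.3), _cohort(0.2), 40, direction="sideways")

    def test_too_few_samples_errors(self):
        with pytest.raises(ValueError):
            classify_delta_h([0.3], [0.2, 0.1], 40)


class TestClassifyNe:
    @pytest.mark.parametrize(
        "ne,expected",
        [
            (600, Status.ACCEPTABLE),
            (500, Status.ACCEPTABLE),  # boundary: >= 500 acceptable
            (499.9, Status.WARNING),
            (120, Status.WARNING),
            (50.1, Status.WARNING),
            (50, Status.ALARM),  # boundary: strict 50 < Ne needed for Warning
            (30, Status.ALARM),
        ],
    )
    def test_thresholds(self, ne, expected):
        assert classify_ne(ne) == expected

    def test_monotone_in_ne(self):
        order = {Status.ACCEPTABLE: 0, Status.WARNING: 1, Status.ALARM: 2}
        rng = np.random.default_rng(0)
        nes = np.sort(rng.uniform(1, 1000, 50))[::-1]
        ranks = [order[classify_ne(ne)] for ne in nes]
        assert (np.diff(ranks) >= 0).all()

    def test_nonpositive_errors(self):
        with pytest.raises(ValueError):
            classify_ne(0)


class TestFstToMigrants:
    def test_closed_form(self):
        assert fst_to_migrants(0.2) == pytest.approx(1.0)
        assert fst_to_migrants(0.05) == pytest.approx(4.75)

    def test_limit_toward_fixation(self):
        assert fst_to_migrants(0.999) < 0.001

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.5])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            fst_to_migrants(bad)


def _fst_track(values, jitter=0.0, seed=0):
    rng = np.random.default_rng(seed)
    n = len(values)
    frame = pd.DataFrame(
        {
            "chrom": ["chr1"] * n,
            "start": np.arange(n) * 1000,
            "end": np.arange(n) * 1000 + 1000,
            "n_sites": 5,
            "value": np.asarray(values) + rng.normal(0, jitter, n),
        }
    )
    return DiversityTrack(frame, "fst", ("A", "B"), 1000, 1000)


class TestClassifyDeltaFst:
    def test_extinction_is_alarm(self):
        t = _fst_track([0.05] * 12)
        r = classify_delta_fst(t, t, populations_maintained=False)
        assert r.status == Status.ALARM

    def test_no_change_acceptable(self):
        t = _fst_track([0.05] * 12)
        r = classify_delta_fst(t, t)
        assert not r.significant
        assert r.status == Status.ACCEPTABLE

    def test_doubling_fst_is_alarm(self):
        # 0.05 -> 0.10: Nm 4.75 -> 2.25, a 52.6% migration loss
        r = classify_delta_fst(_fst_track([0.05] * 12), _fst_track([0.10] * 12))
        assert r.significant
        assert r.nm_t1 == pytest.approx(4.75)
        assert r.nm_t2 == pytest.approx(2.25)
        assert r.status == Status.ALARM

    def test_moderate_migration_loss_is_warning(self):
        # Nm 4.75 -> 3.325 (-30%): Warning band
        f2 = 1.0 / (4 * 3.325 + 1)
        r = classify_delta_fst(_fst_track([0.05] * 12), _fst_track([f2] * 12))
        assert r.status == Status.WARNING

    def test_migration_gain_bands(self):
        f_warn = 1.0 / (4 * 4.75 * 1.6 + 1)  # +60% migrants
        f_alarm = 1.0 / (4 * 4.75 * 2.5 + 1)  # +150% migrants
        assert classify_delta_fst(
            _fst_track([0.05] * 12), _fst_track([f_warn] * 12)
        ).status == Status.WARNING
        assert classify_delta_fst(
            _fst_track([0.05] * 12), _fst_track([f_alarm] * 12)
        ).status == Status.ALARM

    def test_too_few_windows_errors(self):
        t = _fst_track([0.05] * 5)
        with pytest.raises(ValueError, match="10 shared"):
            classify_delta_fst(t, t)
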