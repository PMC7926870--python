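"""Spectrum/cohort I/O: parsing dialects, round trips, replicate handling."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from leukoftir.core import (
    CohortSet,
    Spectrum,
    SpectrumFormatError,
    ValidationError,
    average_replicates,
    load_cohort,
    read_manifest,
    read_spectrum,
    write_cohort,
    write_spectrum,
)


def _spec(k, a, **kw):
    return Spectrum(sample_id=kw.pop("sample_id", "s"), wavenumbers=k, absorbance=a, **kw)


class TestSpectrumInvariants:
    def test_rejects_bad_grids(self):
        with pytest.raises(ValidationError):
            _spec([1000, 1000, 1004], [1, 2, 3])  # duplicate wavenumber
        with pytest.raises(ValidationError):
            _spec([1004, 1002, 1000], [1, 2, 3])  # descending
        with pytest.raises(ValidationError):
            _spec([1000, 1002], [1, 2])  # too short
        with pytest.raises(ValidationError):
            _spec([-1, 1000, 1002], [1, 2, 3])  # non-positive wavenumber
        with pytest.raises(ValidationError):
            _spec([1000, 1002, 1004], [1, np.nan, 3])  # non-finite

    def test_rejects_unknown_group(self):
        with pytest.raises(ValidationError):
            _spec([1000, 1002, 1004], [1, 2, 3], group="ALL")


class TestReadSpectrum:
    def test_csv_direct_parse(self, tmp_path):
        p = tmp_path / "a.csv"
        p.write_text("1000,0.1\n1002,0.2\n1004,0.1\n")
        s = read_spectrum(p)
        assert len(s) == 3
        assert np.array_equal(s.wavenumbers, [1000, 1002, 1004])
        assert np.array_equal(s.absorbance, [0.1, 0.2, 0.1])

    def test_descending_order_sorted(self, tmp_path):
        up = tmp_path / "up.csv"
        down = tmp_path / "down.csv"
        up.write_text("1000,0.1\n1002,0.2\n1004,0.1\n")
        down.write_text("1004,0.1\n1002,0.2\n1000,0.1\n")
        a, b = read_spectrum(up), read_spectrum(down)
        assert np.array_equal(a.wavenumbers, b.wavenumbers)
        assert np.array_equal(a.absorbance, b.absorbance)

    def test_header_row_is_skipped(self, tmp_path):
        p = tmp_path / "h.csv"
        p.write_text("wavenumber_cm-1,absorbance\n1000,0.1\n1002,0.2\n1004,0.1\n")
        assert len(read_spectrum(p)) == 3

    def test_unparsable_line_names_position(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("1000,0.1\nnot,numbers\n1004,0.1\n")
        with pytest.raises(SpectrumFormatError, match=":2"):
            read_spectrum(p)

    def test_duplicate_wavenumbers_rejected(self, tmp_path):
        p = tmp_path / "dup.csv"
        p.write_text("1000,0.1\n1000,0.2\n1004,0.1\n")
        with pytest.raises(ValidationError):
            read_spectrum(p)

    def test_csv_round_trip(self, tmp_path, rng):
        k = np.linspace(800, 3500, 301)
        a = rng.normal(size=301)
        s = _spec(k, a)
        write_spectrum(s, tmp_path / "rt.csv")
        back = read_spectrum(tmp_path / "rt.csv")
        assert np.max(np.abs(back.absorbance - a)) < 1e-9
        assert np.max(np.abs(back.wavenumbers - k)) < 1e-9


class TestJcamp:
    def _write_jcamp_xydata(self, path, k, a):
        lines = ["##TITLE=test", "##JCAMP-DX=4.24", "##XUNITS=1/CM", "##YUNITS=ABSORBANCE",
                 f"##FIRSTX={k[0]}", f"##LASTX={k[-1]}", f"##NPOINTS={len(k)}",
                 "##XFACTOR=1.0", "##YFACTOR=1.0", "##XYDATA=(X++(Y..Y))"]
        for i in range(0, len(k), 4):
            ys = " ".join(f"{v:.8f}" for v in a[i : i + 4])
            lines.append(f"{k[i]:.1f} {ys}")
        lines.append("##END=")
        path.write_text("\n".join(lines))

    def _write_jcamp_xypoints(self, path, k, a):
        lines = ["##TITLE=test", "##JCAMP-DX=4.24", "##XYPOINTS=(XY..XY)"]
        lines += [f"{x:.4f}, {y:.8f}" for x, y in zip(k, a)]
        lines.append("##END=")
        path.write_text("\n".join(lines))

    def test_dialect_stability(self, tmp_path):
        """CSV, XYDATA and XYPOINTS encodings of one trace agree."""
        k = 1000.0 + 2.0 * np.arange(12)
        a = np.exp(-0.5 * ((k - 1010) / 4.0) ** 2)
        (tmp_path / "t.csv").write_text(
            "\n".join(f"{x},{y:.8f}" for x, y in zip(k, a))
        )
        self._write_jcamp_xydata(tmp_path / "t.jdx", k, a)
        self._write_jcamp_xypoints(tmp_path / "p.jdx", k, a)
        ref = read_spectrum(tmp_path / "t.csv")
        for name in ("t.jdx", "p.jdx"):
            s = read_spectrum(tmp_path / name, format="jcamp")
            assert np.allclose(s.wavenumbers, ref.wavenumbers, atol=1e-6)
            assert np.allclose(s.absorbance, ref.absorbance, atol=1e-7)

    def test_yfactor_applied(self, tmp_path):
        k = 1000.0 + 2.0 * np.arange(8)
        a = np.linspace(0.0, 1.0, 8)
        p = tmp_path / "f.jdx"
        lines = ["##TITLE=t", "##YFACTOR=0.5", "##XYPOINTS=(XY..XY)"]
        lines += [f"{x}, {y}" for x, y in zip(k, a * 2.0)]
        lines.append("##END=")
        p.write_text("\n".join(lines))
        s = read_spectrum(p, format="jcamp")
        assert np.allclose(s.absorbance, a)

    def test_missing_data_block(self, tmp_path):
        p = tmp_path / "empty.jdx"
        p.write_text("##TITLE=t\n##END=\n")
        with pytest.raises(SpectrumFormatError):
            read_spectrum(p, format="jcamp")


class TestCohort:
    def _write_cohort_files(self, tmp_path, n_samples=2, reps=2):
        rows = []
        k = np.array([1000.0, 1002.0, 1004.0])
        for i in range(n_samples):
            for r in range(1, reps + 1):
                f = tmp_path / f"s{i}_{r}.csv"
                f.write_text("\n".join(f"{x},{0.1 * (i + r)}" for x in k))
                rows.append(
                    {"sample_id": f"s{i}", "group": "control", "file_path": f.name,
                     "replicate": r, "wbc": 5.0, "blasts": np.nan}
                )
        m = tmp_path / "manifest.csv"
        pd.DataFrame(rows).to_csv(m, index=False)
        return m

    def test_load_counts_and_ids(self, tmp_path):
        m = self._write_cohort_files(tmp_path)
        cohort = load_cohort(m)
        assert len(cohort) == 4
        assert cohort.sample_ids == ["s0", "s1"]
        assert cohort.spectra[0].meta["wbc"] == 5.0

    def test_unrecognized_group_label(self, tmp_path):
        m = self._write_cohort_files(tmp_path)
        df = pd.read_csv(m)
        df.loc[0, "group"] = "ALL"
        df.to_csv(m, index=False)
        with pytest.raises(ValidationError):
            load_cohort(m)

    def test_missing_file_names_sample(self, tmp_path):
        m = self._write_cohort_files(tmp_path)
        df = pd.read_csv(m)
        df.loc[0, "file_path"] = "nope.csv"
        df.to_csv(m, index=False)
        with pytest.raises(FileNotFoundError, match="s0"):
            load_cohort(m)

    def test_duplicate_replicate_rejected(self, tmp_path):
        m = self._write_cohort_files(tmp_path)
        df = pd.read_csv(m)
        df.loc[1, "replicate"] = 1  # collide with row 0
        df.to_csv(m, index=False)
        with pytest.raises(ValidationError):
            load_cohort(m)

    def test_manifest_missing_columns(self, tmp_path):
        p = tmp_path / "m.csv"
        pd.DataFrame({"sample_id": ["a"], "group": ["control"]}).to_csv(p, index=False)
        with pytest.raises(ValidationError):
            read_manifest(p)

    def test_synthetic_round_trip(self, tmp_path, noiseless_cohort):
        """Write a generated cohort to disk, reload, compare exactly."""
        _, cohort, _ = noiseless_cohort
        m = write_cohort(cohort, tmp_path / "cohort")
        back = load_cohort(m)
        assert len(back) == len(cohort)
        orig = {(s.sample_id, s.replicate): s for s in cohort}
        for s in back:
            o = orig[(s.sample_id, s.replicate)]
            assert s.group == o.group
            assert np.max(np.abs(s.absorbance - o.absorbance)) < 1e-12
            assert s.meta.get("wbc") == pytest.approx(o.meta.get("wbc"))


class TestAverageReplicates:
    def _cohort(self, arrays, ids=None):
        k = np.array([1000.0, 1002.0, 1004.0])
        ids = ids or ["s"] * len(arrays)
        return CohortSet(
            [
                Spectrum(sample_id=i, replicate=r + 1, wavenumbers=k, absorbance=np.asarray(a))
                for r, (i, a) in enumerate(zip(ids, arrays))
            ]
        )

    def test_identical_replicates_idempotent(self):
        c = self._cohort([[1, 2, 3], [1, 2, 3]])
        out = average_replicates(c)
        assert len(out) == 1
        assert np.array_equal(out.spectra[0].absorbance, [1, 2, 3])

    def test_mean_of_a_and_3a(self):
        a = np.array([1.0, 2.0, 3.0])
        out = average_replicates(self._cohort([a, 3 * a]))
        assert np.allclose(out.spectra[0].absorbance, 2 * a)

    def test_matches_brute_force_mean(self, rng):
        reps = [rng.normal(size=3) for _ in range(3)]
        out = average_replicates(self._cohort(reps))
        brute = np.zeros(3)
        for r in reps:
            brute += r
        brute /= 3
        assert np.max(np.abs(out.spectra[0].absorbance - brute)) < 1e-12

    def test_commutes_with_linear_ops(self, rng):
        """mean(c·A + d) == c·mean(A) + d pointwise."""
        reps = [rng.normal(size=3) for _ in range(3)]
        direct = average_replicates(self._cohort([2.0 * r + 1.0 for r in reps]))
        via = average_replicates(self._cohort(reps))
        assert np.allclose(
            direct.spectra[0].absorbance, 2.0 * via.spectra[0].absorbance + 1.0
        )

    def test_different_grids_rejected(self):
        k1 = np.array([1000.0, 1002.0, 1004.0])
        k2 = np.array([1000.0, 1003.0, 1004.0])
        c = CohortSet(
            [
                Spectrum(sample_id="s", replicate=1, wavenumbers=k1, absorbance=np.ones(3)),
                Spectrum(sample_id="s", replicate=2, wavenumbers=k2, absorbance=np.ones(3)),
            ]
        )
        with pytest.raises(ValidationError, match="resample"):
            average_replicates(c)
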