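"""mzML round trips, vDIA window handling, and acquisition validation."""

import subprocess
import textwrap

import numpy as np
import pytest

from honeyscreen.spectra_io import (
    CANONICAL_WINDOWS,
    CentroidSpectrum,
    LcmsRun,
    MzmlParseError,
    ProfileModeError,
    VdiaWindow,
    WindowError,
    match_window,
    read_metadata,
    read_run,
    write_run,
)


def _example_run(n_windows=0):
    scans = [
        CentroidSpectrum(0.0, 1, np.array([150.0, 300.1234567]), np.array([1000.0, 0.0])),
        CentroidSpectrum(1.0, 1, np.empty(0), np.empty(0)),
    ]
    for i in range(n_windows):
        w = CANONICAL_WINDOWS[i]
        scans.append(
            CentroidSpectrum(1.0 + 0.1 * (i + 1), 2, np.array([w.fragment_low + 5.0]),
                             np.array([42.0]), window=w)
        )
    return LcmsRun("sampleA", "HILIC_neg", scans=scans, device_id="dev9")


def assert_runs_equal(a: LcmsRun, b: LcmsRun):
    assert len(a.scans) == len(b.scans)
    for sa, sb in zip(a.scans, b.scans):
        assert sa.rt == pytest.approx(sb.rt, abs=1e-3)
        assert sa.ms_level == sb.ms_level
        assert sa.window == sb.window
        np.testing.assert_allclose(sa.mz, sb.mz, rtol=1e-6)
        np.testing.assert_allclose(sa.intensity, sb.intensity, rtol=1e-6)


@pytest.mark.parametrize("n_windows", [0, 1, 6])
def test_round_trip_identity(tmp_path, n_windows):
    """write_run then read_run reproduces scan count, RTs, windows, peak lists."""
    run = _example_run(n_windows)
    path = write_run(run, tmp_path / "a.mzML")
    back = read_run(path, "HILIC_neg")
    assert back.sample_id == "sampleA" and back.device_id == "dev9"
    assert_runs_equal(run, back)
    windows = [s.window for s in back.scans if s.ms_level == 2]
    assert windows == list(CANONICAL_WINDOWS[:n_windows])


def test_empty_run_round_trips(tmp_path):
    run = LcmsRun("empty", "RP_pos", scans=[])
    back = read_run(write_run(run, tmp_path / "e.mzML"), "RP_pos")
    assert back.scans == []


def test_ms2_window_annotation_covers_first_window(tmp_path):
    """Isolation 100-200 Da maps to the canonical (100, 200, 50, 225) window."""
    run = _example_run(1)
    back = read_run(write_run(run, tmp_path / "w.mzML"), "HILIC_neg")
    (w,) = [s.window for s in back.scans if s.ms_level == 2]
    assert w == VdiaWindow(100.0, 200.0, 50.0, 225.0)


def test_canonical_windows_tile_full_scan_range():
    """Six windows, contiguous precursor coverage of 100-1500 Da."""
    assert len(CANONICAL_WINDOWS) == 6
    ordered = sorted(CANONICAL_WINDOWS, key=lambda w: w.precursor_low)
    assert ordered[0].precursor_low == 100.0 and ordered[-1].precursor_high == 1500.0
    for a, b in zip(ordered, ordered[1:]):
        assert a.precursor_high == b.precursor_low


def test_match_window_tolerates_jitter_but_not_strangers():
    w = match_window(99.8, 200.3)
    assert w.precursor_low == 100.0
    with pytest.raises(WindowError):
        match_window(550.0, 850.0)  # midpoint 700, 50 Da from the nearest canonical


def test_profile_spectra_rejected(tmp_path):
    path = write_run(_example_run(), tmp_path / "p.mzML")
    text = path.read_text().replace(
        'accession="MS:1000127" name="centroid spectrum"',
        'accession="MS:1000128" name="profile spectrum"',
    )
    path.write_text(text)
    with pytest.raises(ProfileModeError):
        read_run(path, "HILIC_neg")


def test_malformed_file_raises_parse_error(tmp_path):
    bad = tmp_path / "bad.mzML"
    bad.write_text("<mzML><run></mzML>")
    with pytest.raises(MzmlParseError):
        read_run(bad, "HILIC_neg")
    notxml = tmp_path / "not.mzML"
    notxml.write_text("sample_id,foo\n1,2\n")
    with pytest.raises(MzmlParseError):
        read_run(notxml, "HILIC_neg")


def test_minute_valued_rt_converted_to_seconds(tmp_path):
    path = write_run(_example_run(), tmp_path / "m.mzML")
    text = path.read_text().replace(
        'name="scan start time" value="0.0" unitCvRef="UO" unitAccession="UO:0000010" unitName="second"',
        'name="scan start time" value="0.5" unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"',
    )
    path.write_text(text)
    back = read_run(path, "HILIC_neg")  # scans re-sorted by RT after conversion
    assert sorted(s.rt for s in back.scans)[-1] == pytest.approx(30.0)


def test_mzr_reads_written_mzml(tmp_path):
    """Independent oracle: Bioconductor mzR parses our mzML identically."""
    pytest.importorskip("numpy")
    run = _example_run(2)
    path = write_run(run, tmp_path / "oracle.mzML")
    script = textwrap.dedent(f"""
        suppressMessages(library(mzR))
        f <- openMSfile("{path}")
        h <- header(f)
        cat(nrow(h), h$msLevel, sprintf("%.6f", h$retentionTime), "\\n")
        p <- peaks(f, 1)
        cat(sprintf("%.6f", p[,1]), sprintf("%.1f", p[,2]), "\\n")
    """)
    try:
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
        )
    except FileNotFoundError:
        pytest.skip("Rscript unavailable")
    assert out.returncode == 0, out.stderr
    fields = out.stdout.split()
    assert fields[0] == "4"  # 2 MS1 + 2 MS2 scans
    assert fields[1:5] == ["1", "1", "2", "2"]  # MS levels
    assert [float(x) for x in fields[5:9]] == pytest.approx([0.0, 1.0, 1.1, 1.2], abs=1e-3)
    assert [float(x) for x in fields[9:11]] == pytest.approx([150.0, 300.1234567], abs=1e-6)


def test_spectrum_invariants_enforced():
    with pytest.raises(ValueError):
        CentroidSpectrum(0.0, 1, np.array([2.0, 1.0]), np.array([1.0, 1.0]))
    with pytest.raises(ValueError):
        CentroidSpectrum(0.0, 1, np.array([1.0]), np.array([-1.0]))
    with pytest.raises(ValueError):
        CentroidSpectrum(0.0, 2, np.array([1.0]), np.array([1.0]))  # MS2 needs window
    with pytest.raises(ValueError):
        CentroidSpectrum(0.0, 1, np.array([1.0]), np.array([1.0]), window=CANONICAL_WINDOWS[0])


def test_validate_run_checks_acquisition_scheme():
    from honeyscreen.spectra_io import validate_run

    validate_run(_example_run(6))  # canonical acquisition passes
    out_of_range = LcmsRun(
        "bad",
        "HILIC_neg",
        scans=[CentroidSpectrum(0.0, 1, np.array([50.0]), np.array([1.0]))],
    )
    with pytest.raises(ValueError, match="full-scan range"):
        validate_run(out_of_range)


def test_metadata_schema_validation(tmp_path):
    good = tmp_path / "meta.csv"
    good.write_text(
        "sample_id,honey_id,syrup,proportion_pct,device_id,mode,path\n"
        "s1,H01,none,0,dev1,HILIC_neg,s1.mzML\n"
        "s2,H01,rice,10,dev1,RP_pos,s2.mzML\n"
    )
    df = read_metadata(good)
    assert list(df["sample_id"]) == ["s1", "s2"]
    bad = tmp_path / "bad.csv"
    bad.write_text(
        "sample_id,honey_id,syrup,proportion_pct,device_id,mode,path\n"
        "s1,H01,rice,0,dev1,HILIC_neg,s1.mzML\n"
    )
    with pytest.raises(ValueError, match="proportion"):
        read_metadata(bad)
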