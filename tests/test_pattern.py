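"""2D fracture pattern generation, validation and persistence tests."""

import math

import numpy as np
import pytest

from osteofract.errors import FormatError, ParameterError
from osteofract.pattern import (
    ForensicCriteria,
    FracturePattern2D,
    Polyline,
    count_regions,
    default_criteria,
    generate_parametric_pattern,
    read_pattern,
    validate_pattern,
    write_pattern,
)


def test_transverse_is_constant_height_loop():
    pat = generate_parametric_pattern("transverse", {"v0": 50.0, "waviness": 0.0})
    (line,) = pat.lines_outer
    assert line.closed
    assert np.allclose(line.points[:, 1], 50.0)
    assert line.winding() == 1


def test_oblique_rise_matches_slope_closed_form():
    """Over one wrap the line rises by C tan(alpha)."""
    C = 62.832
    pat = generate_parametric_pattern(
        "oblique", {"angle_deg": 30.0, "circumference": C}
    )
    (line,) = pat.lines_outer
    rise = line.points[:, 1].max() - line.points[:, 1].min()
    assert rise == pytest.approx(C * math.tan(math.radians(30.0)), rel=1e-12)
    assert line.closed and line.winding() == 1


# closed-form region counts: one per winding loop plus one per detached
# loop, plus the base band region (loops do not intersect by construction)
@pytest.mark.parametrize("ftype,expected_regions,expected_lines", [
    ("transverse", 2, 1),
    ("oblique", 2, 1),
    ("spiral", 2, 1),
    ("wedge", 3, 2),
    ("comminuted", 4, 3),
])
def test_region_counts_per_type(ftype, expected_regions, expected_lines):
    pat = generate_parametric_pattern(ftype, seed=2)
    assert len(pat.lines_outer) == expected_lines
    assert count_regions(pat.lines_outer) == expected_regions


def test_parameter_range_enforced():
    with pytest.raises(ParameterError):
        generate_parametric_pattern("oblique", {"angle_deg": 85.0})
    with pytest.raises(ParameterError):
        generate_parametric_pattern("transverse", {"bogus": 1.0})
    with pytest.raises(ParameterError):
        generate_parametric_pattern("shear")


def test_inner_equals_outer_without_offset_or_noise():
    pat = generate_parametric_pattern("comminuted", inner_offset=0.0,
                                      inner_noise=0.0, seed=4)
    for lo, li in zip(pat.lines_outer, pat.lines_inner):
        assert np.array_equal(lo.points, li.points)


def test_inner_noise_bounded():
    off, amp = 0.7, 0.3
    pat = generate_parametric_pattern("transverse", inner_offset=off,
                                      inner_noise=amp, seed=11)
    dv = pat.lines_inner[0].points[:, 1] - pat.lines_outer[0].points[:, 1]
    assert np.abs(dv - off).max() <= amp + 1e-12


def test_validation_accepts_defaults_and_is_monotone():
    """Every default pattern passes its type's criteria; relaxing every
    bound never flips valid -> invalid."""
    for ftype in ("transverse", "oblique", "spiral", "wedge", "comminuted"):
        pat = generate_parametric_pattern(ftype, seed=1)
        crit = default_criteria(ftype)
        res = validate_pattern(pat, crit)
        assert res.valid, [c.name for c in res.failures()]
        relaxed = ForensicCriteria(
            n_lines=(0, 99), total_length=(0.0, 1e3),
            n_fragments=(0, 99), max_v_extent=1e3,
            reference_circumference=crit.reference_circumference,
        )
        assert validate_pattern(pat, relaxed).valid


def test_validation_reports_failures():
    empty = FracturePattern2D(lines_outer=[], lines_inner=[],
                              fracture_type="transverse")
    res = validate_pattern(empty, default_criteria("transverse"))
    assert not res.valid
    assert any("line count" in c.name for c in res.failures())

    pat = generate_parametric_pattern("transverse", seed=0)
    strict = ForensicCriteria(n_lines=(1, 1), total_length=(0.5, 5.0),
                              n_fragments=(3, 3))  # transverse gives 2
    res = validate_pattern(pat, strict)
    assert not res.valid
    assert any("fragment" in c.name for c in res.failures())


def test_json_round_trip(tmp_path):
    pat = generate_parametric_pattern("wedge", seed=3, inner_offset=0.5,
                                      inner_noise=0.3)
    path = tmp_path / "p.json"
    write_pattern(pat, path)
    back = read_pattern(path)
    assert back.fracture_type == pat.fracture_type
    assert back.source == pat.source
    for a, b in zip(pat.lines_outer + pat.lines_inner,
                    back.lines_outer + back.lines_inner):
        assert a.closed == b.closed
        assert np.array_equal(a.points, b.points)


def test_read_rejects_out_of_range_u(tmp_path):
    path = tmp_path / "bad.json"
    path.write_text(
        '{"schema": 1, "type": "transverse", "source": "drawn",'
        ' "lines_outer": [{"points": [[0.1, 0], [1.2, 5]], "closed": false}],'
        ' "lines_inner": []}'
    )
    with pytest.raises(FormatError, match=r"/lines_outer/0/points/1/0"):
        read_pattern(path)


def test_read_fills_missing_inner(tmp_path, caplog):
    path = tmp_path / "outer_only.json"
    path.write_text(
        '{"schema": 1, "type": "transverse", "source": "drawn",'
        ' "lines_outer": [{"points": [[0.0, 0], [0.5, 0]], "closed": true}],'
        ' "lines_inner": []}'
    )
    import logging
    with caplog.at_level(logging.WARNING, logger="osteofract"):
        pat = read_pattern(path)
    assert len(pat.lines_inner) == 1
    assert np.array_equal(pat.lines_inner[0].points, pat.lines_outer[0].points)
    assert any("inner" in r.message for r in caplog.records)


def test_polyline_invariants():
    with pytest.raises(ValueError):
        Polyline(np.array([[0.5, 1.0]]))           # too short
    with pytest.raises(ValueError):
        Polyline(np.array([[1.0, 0.0], [0.5, 1.0]]))  # u out of range


def test_criteria_round_trip():
    c = default_criteria("comminuted")
    assert ForensicCriteria.from_dict(c.to_dict()) == c
    with pytest.raises(ValueError):
        ForensicCriteria(n_lines=(3, 1))
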