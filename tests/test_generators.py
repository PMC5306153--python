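"""Connectivity generators: metadata parsing, sandboxed execution, oracle
equivalence of the built-ins, caching and persistence."""

import math
import random

import numpy as np
import pytest

from spinemk.generators import (
    FIXED_RADIUS_SCRIPT,
    GAUSSIAN_FIELD_SCRIPT,
    GenerationRecipe,
    GeneratorExecutionError,
    GeneratorMetadataError,
    load_with_recipe,
    needs_regeneration,
    parse_generator_metadata,
    persist_with_recipe,
    regenerate,
    run_generator,
)
from spinemk.layouts import CoordinateSet, grid_layout, random_box_layout


class TestMetadataParsing:
    def test_builtin_gaussian_field(self):
        script = parse_generator_metadata(GAUSSIAN_FIELD_SCRIPT)
        assert [p[0] for p in script.params] == ["sigma", "amplitude", "seed"]
        assert script.has_weight and not script.has_delay
        assert script.entry_name == "gaussian_field"

    def test_builtin_fixed_radius(self):
        script = parse_generator_metadata(FIXED_RADIUS_SCRIPT)
        assert len(script.params) == 3
        assert script.has_delay and not script.has_weight
        assert script.params[0] == ("radius", 0, 0)

    def test_bare_script_has_no_params_or_flags(self):
        script = parse_generator_metadata(
            "def connect(srclocs, dstlocs):\n    return []\n")
        assert script.params == ()
        assert not script.has_weight and not script.has_delay

    def test_parname_arity_mismatch(self):
        text = ("#PARNAME: a\n#PARNAME: b\n#PARNAME: c\n"
                "def f(srclocs, dstlocs, a):\n    return []\n")
        with pytest.raises(GeneratorMetadataError, match="3 #PARNAME"):
            parse_generator_metadata(text)

    def test_duplicate_grid_cell(self):
        text = ("#PARNAME: a\n#LOC: 0,0\n#PARNAME: b\n#LOC: 0,0\n"
                "def f(srclocs, dstlocs, a, b):\n    return []\n")
        with pytest.raises(GeneratorMetadataError, match="grid cell"):
            parse_generator_metadata(text)

    def test_missing_entry_point(self):
        with pytest.raises(GeneratorMetadataError, match="entry point"):
            parse_generator_metadata("def f(x, y):\n    return []\n")


class TestRunGenerator:
    def test_coincident_points_within_radius(self):
        script = parse_generator_metadata(FIXED_RADIUS_SCRIPT)
        pts = CoordinateSet(np.zeros((1, 3)))
        clist = run_generator(script, pts, pts, (1.0, 1.0, 0.0))
        assert clist.triplets == ((0, 0, 0.0),)

    def test_points_outside_radius_not_connected(self):
        script = parse_generator_metadata(FIXED_RADIUS_SCRIPT)
        src = CoordinateSet(np.array([[0.0, 0.0, 0.0]]))
        dst = CoordinateSet(np.array([[5.0, 0.0, 0.0]]))
        clist = run_generator(script, src, dst, (3.0, 1.0, 0.0))
        assert len(clist) == 0

    def test_delay_is_distance_over_velocity_plus_base(self):
        script = parse_generator_metadata(FIXED_RADIUS_SCRIPT)
        src = CoordinateSet(np.array([[0.0, 0.0, 0.0]]))
        dst = CoordinateSet(np.array([[6.0, 8.0, 0.0]]))  # distance 10
        clist = run_generator(script, src, dst, (20.0, 2.0, 1.5))
        assert clist.triplets[0][2] == pytest.approx(10.0 / 2.0 + 1.5)

    def test_wrong_value_count(self):
        script = parse_generator_metadata(FIXED_RADIUS_SCRIPT)
        pts = CoordinateSet(np.zeros((1, 3)))
        with pytest.raises(ValueError, match="parameter value"):
            run_generator(script, pts, pts, (1.0,))

    def test_script_exception_is_wrapped(self):
        script = parse_generator_metadata(
            "def f(srclocs, dstlocs):\n    return 1 / 0\n")
        pts = CoordinateSet(np.zeros((1, 3)))
        with pytest.raises(GeneratorExecutionError, match="ZeroDivision"):
            run_generator(script, pts, pts, ())

    def test_out_of_range_index_rejected(self):
        script = parse_generator_metadata(
            "def f(srclocs, dstlocs):\n    return [(0, 99)]\n")
        pts = CoordinateSet(np.zeros((1, 3)))
        with pytest.raises(GeneratorExecutionError, match="out of range"):
            run_generator(script, pts, pts, ())

    def test_sandbox_has_no_file_access(self):
        script = parse_generator_metadata(
            "def f(srclocs, dstlocs):\n"
            "    open('/etc/hostname')\n"
            "    return []\n")
        pts = CoordinateSet(np.zeros((1, 3)))
        with pytest.raises(GeneratorExecutionError, match="open"):
            run_generator(script, pts, pts, ())


class TestOracleEquivalence:
    def test_fixed_radius_matches_direct_implementation(self):
        src = random_box_layout(150, 100.0, seed=11)
        dst = random_box_layout(200, 100.0, seed=12)
        script = parse_generator_metadata(FIXED_RADIUS_SCRIPT)
        clist = run_generator(script, src, dst, (30.0, 2.0, 0.5))
        # independent O(n^2) oracle on the raw arrays
        diff = src.coordinates[:, None, :] - dst.coordinates[None, :, :]
        dist = np.sqrt((diff**2).sum(axis=2))
        expected = [(i, j, dist[i, j] / 2.0 + 0.5)
                    for i in range(150) for j in range(200)
                    if dist[i, j] <= 30.0]
        assert len(clist) == len(expected)
        for got, want in zip(clist.triplets, expected):
            assert got[:2] == want[:2]
            assert got[2] == pytest.approx(want[2])

    def test_gaussian_field_matches_direct_implementation(self):
        src = grid_layout(100, 10)
        dst = grid_layout(100, 10)
        script = parse_generator_metadata(GAUSSIAN_FIELD_SCRIPT)
        sigma, amplitude, seed = 2.0, 1.5, 99.0
        clist = run_generator(script, src, dst, (sigma, amplitude, seed))
        # independent reimplementation, same pair order and stream
        rng = random.Random(int(seed))
        expected = []
        for i, s in enumerate(src.as_tuples()):
            for j, d in enumerate(dst.as_tuples()):
                d2 = sum((a - b) ** 2 for a, b in zip(s, d))
                g = math.exp(-d2 / (2 * sigma * sigma))
                if rng.random() < g:
                    expected.append((i, j, amplitude * g))
        assert len(clist) == len(expected)
        assert clist.weights is not None
        for (gs, gd, _), w, (es, ed, ew) in zip(clist.triplets, clist.weights,
                                                expected):
            assert (gs, gd) == (es, ed)
            assert w == pytest.approx(ew)

    def test_fixed_radius_symmetric_on_equal_coordinate_sets(self):
        pts = random_box_layout(60, 50.0, seed=21)
        script = parse_generator_metadata(FIXED_RADIUS_SCRIPT)
        fwd = run_generator(script, pts, pts, (15.0, 1.0, 0.0))
        pairs = {t[:2] for t in fwd.triplets}
        assert all((j, i) in pairs for i, j in pairs)


class TestCaching:
    def _recipe(self):
        return GenerationRecipe(FIXED_RADIUS_SCRIPT, (10.0, 1.0, 0.0), 5, 5)

    def test_identical_everything_no_regeneration(self):
        r = self._recipe()
        assert not needs_regeneration(r, FIXED_RADIUS_SCRIPT,
                                      (10.0, 1.0, 0.0), 5, 5)

    def test_parameter_change_triggers(self):
        r = self._recipe()
        assert needs_regeneration(r, FIXED_RADIUS_SCRIPT, (12.5, 1.0, 0.0),
                                  5, 5)

    def test_whitespace_only_edit_triggers(self):
        r = self._recipe()
        assert needs_regeneration(r, FIXED_RADIUS_SCRIPT + "\n",
                                  (10.0, 1.0, 0.0), 5, 5)

    def test_size_change_triggers(self):
        r = self._recipe()
        assert needs_regeneration(r, FIXED_RADIUS_SCRIPT, (10.0, 1.0, 0.0),
                                  6, 5)

    def test_regeneration_is_bit_exact(self):
        src = random_box_layout(40, 60.0, seed=31)
        dst = random_box_layout(40, 60.0, seed=32)
        script = parse_generator_metadata(GAUSSIAN_FIELD_SCRIPT)
        original = run_generator(script, src, dst, (5.0, 2.0, 7.0))
        again = regenerate(original.recipe, src, dst)
        assert again.triplets == original.triplets
        assert again.weights == original.weights


class TestPersistence:
    def test_all_to_all_with_recipe_has_every_row(self):
        src = grid_layout(7, 7)
        script = parse_generator_metadata(
            "def f(srclocs, dstlocs):\n"
            "    return [(i, j) for i in range(len(srclocs))"
            " for j in range(len(dstlocs))]\n")
        clist = run_generator(script, src, src, ())
        xml = persist_with_recipe(clist, clist.recipe)
        assert xml.count("<Connection ") == 49  # oracle: 7 * 7
        restored = load_with_recipe(xml)
        assert restored.triplets == clist.triplets
        assert restored.recipe == clist.recipe

    def test_fragment_without_annotations_still_loads(self):
        src = grid_layout(3, 3)
        script = parse_generator_metadata(FIXED_RADIUS_SCRIPT)
        clist = run_generator(script, src, src, (1.5, 1.0, 0.0))
        xml = persist_with_recipe(clist, clist.recipe)
        import xml.etree.ElementTree as ET
        from spinemk.network import ANNOTATION_NS
        root = ET.fromstring(xml)
        for ann in root.findall(f"{{{ANNOTATION_NS}}}Annotations"):
            root.remove(ann)
        stripped = ET.tostring(root, encoding="unicode")
        plain = load_with_recipe(stripped)
        assert plain.triplets == clist.triplets
        assert plain.recipe is None

    def test_load_save_stable(self):
        src = grid_layout(4, 2)
        script = parse_generator_metadata(FIXED_RADIUS_SCRIPT)
        clist = run_generator(script, src, src, (2.0, 1.0, 0.0))
        xml = persist_with_recipe(clist, clist.recipe)
        loaded = load_with_recipe(xml)
        assert persist_with_recipe(loaded, loaded.recipe) == xml
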