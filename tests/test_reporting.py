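"""Annotated output, TSV export round-trips, and the command-line front end."""

import json

import numpy as np
import pytest
from click.testing import CliRunner

import flycount as fc
from flycount.cli import main as cli_main
from conftest import make_object


class TestAnnotate:
    def test_no_objects_leaves_image_unchanged(self, small_scene_result):
        _, _, result = small_scene_result
        ann = fc.annotate(result.rect, [])
        assert np.array_equal(ann.pixels, np.stack([result.rect.pixels] * 3, axis=-1))

    def test_targets_outlined_green_only(self, small_scene_result):
        _, _, result = small_scene_result
        targets = [o for o in result.objects if o.label is fc.Label.TARGET]
        ann = fc.annotate(result.rect, targets)
        px = ann.pixels.reshape(-1, 3)
        assert (px == (0, 200, 0)).all(axis=1).any()
        assert not (px == (255, 0, 0)).all(axis=1).any()
        assert not (px == (0, 0, 255)).all(axis=1).any()

    def test_outline_colors_follow_labels(self, small_scene_result):
        _, _, result = small_scene_result
        ann = fc.annotate(result.rect, result.objects)
        for obj in result.objects:
            r0, c0, r1, c1 = obj.bbox_px
            patch = ann.pixels[max(r0 - 2, 0) : r1 + 2, max(c0 - 2, 0) : c1 + 2]
            color = np.array(fc.report.LABEL_COLORS[obj.label])
            assert (patch.reshape(-1, 3) == color).all(axis=1).any()


class TestExportTable:
    def test_round_trip_counts(self, small_scene_result, tmp_path):
        _, _, result = small_scene_result
        path = tmp_path / "out.tsv"
        fc.export_table(result.objects, result.report, path)
        rows, summary = fc.parse_table(path)
        assert len(rows) == len(result.objects)
        for name in (
            "n_excluded_small", "n_excluded_large", "n_garbage", "n_targets",
            "n_touching_objects", "touching_total_estimate", "total_estimate",
        ):
            assert summary[name] == getattr(result.report, name)
        assert summary["mean_area_mm2"] == pytest.approx(result.report.mean_area_mm2, abs=1e-4)
        # integer fields are lossless; reals are 4-decimal
        for row, obj in zip(rows, result.objects):
            assert row["id"] == obj.id
            assert row["cluster_estimate"] == obj.cluster_estimate
            assert row["area_mm2"] == pytest.approx(obj.area_mm2, abs=5e-5)

    def test_two_objects_three_content_lines_plus_summary(self, tmp_path):
        objs = [make_object(1), make_object(2)]
        rep = fc.count([make_object(1), make_object(2)])
        path = tmp_path / "two.tsv"
        fc.export_table(objs, rep, path)
        lines = path.read_text().splitlines()
        assert len(lines) == 1 + 2 + 8  # header + objects + summary block
        assert lines[0].startswith("id\tlabel")

    def test_empty_object_list_header_and_zero_summary(self, tmp_path):
        path = tmp_path / "empty.tsv"
        fc.export_table([], fc.CountReport.empty(), path)
        rows, summary = fc.parse_table(path)
        assert rows == []
        assert summary["total_estimate"] == 0

    def test_unwritable_path_raises(self, small_scene_result):
        _, _, result = small_scene_result
        with pytest.raises(fc.InputError):
            fc.export_table(result.objects, result.report, "/nonexistent-dir/x.tsv")


@pytest.fixture(scope="module")
def scene_file(tmp_path_factory):
    spec = fc.SceneSpec(n_singles=12, n_debris=2, seed=42, output_long_side_px=1600)
    image, _ = fc.generate_scene(spec)
    path = tmp_path_factory.mktemp("scenes") / "scene.png"
    import imageio.v3 as iio

    iio.imwrite(path, image)
    return str(path)


class TestCountCli:
    def test_count_prints_total_estimate(self, scene_file):
        res = CliRunner().invoke(cli_main, ["count", scene_file, "--paper-size", "A4"])
        assert res.exit_code == 0
        assert "total_estimate\t12" in res.output

    def test_cli_total_matches_library(self, scene_file):
        res = CliRunner().invoke(cli_main, ["count", scene_file, "--paper-size", "A4", "--json"])
        payload = json.loads(res.output)
        lib = fc.count_file(scene_file, fc.SheetSpec.iso("A4"))
        assert payload["total_estimate"] == lib.report.total_estimate
        assert payload["n_targets"] == lib.report.n_targets

    def test_missing_input_names_path(self):
        res = CliRunner().invoke(cli_main, ["count", "nope.png"])
        assert res.exit_code == 2
        assert "nope.png" in res.output

    def test_custom_paper_size_accepted(self, tmp_path):
        sheet = fc.SheetSpec.custom(200, 150)
        spec = fc.SceneSpec(sheet=sheet, n_singles=6, n_debris=0, seed=9, output_long_side_px=1400)
        image, _ = fc.generate_scene(spec)
        import imageio.v3 as iio

        p = tmp_path / "custom.png"
        iio.imwrite(p, image)
        res = CliRunner().invoke(cli_main, ["count", str(p), "--paper-size", "200x150"])
        assert res.exit_code == 0
        assert "total_estimate\t6" in res.output

    def test_out_dir_writes_table_and_annotation(self, scene_file, tmp_path):
        res = CliRunner().invoke(
            cli_main, ["count", scene_file, "--out-dir", str(tmp_path)]
        )
        assert res.exit_code == 0
        assert (tmp_path / "scene.objects.tsv").exists()
        assert (tmp_path / "scene.annotated.png").exists()

    def test_config_file_overridden_by_flag(self, scene_file, tmp_path):
        cfg = tmp_path / "params.cfg"
        cfg.write_text("min_length = 5\ntouching_factor = 6\n")
        res = CliRunner().invoke(
            cli_main,
            ["count", scene_file, "--config", str(cfg), "--min-length", "3", "--json"],
        )
        assert res.exit_code == 0
        # flag restored min-length to 3, so all 12 flies survive
        assert json.loads(res.output)["total_estimate"] == 12


class TestSimulateAndEvaluateCli:
    def test_simulate_writes_scene_and_truth(self, tmp_path):
        out = tmp_path / "sim.png"
        truth = tmp_path / "truth.tsv"
        res = CliRunner().invoke(
            cli_main,
            ["simulate", "--n-singles", "8", "--clusters", "2", "--seed", "5",
             "--long-side", "1400", "--out", str(out), "--truth", str(truth)],
        )
        assert res.exit_code == 0
        assert out.exists()
        text = truth.read_text()
        assert "true_fly_count\t10" in text

    def test_evaluate_identical_files(self, tmp_path):
        table = "id\tcount\n" + "\n".join(f"s{i}\t{10 + 3 * i}" for i in range(5)) + "\n"
        t = tmp_path / "t.tsv"
        e = tmp_path / "e.tsv"
        t.write_text(table)
        e.write_text(table)
        res = CliRunner().invoke(cli_main, ["evaluate", str(t), str(e), "--json"])
        payload = json.loads(res.output)
        assert payload["mae"] == 0.0
        assert payload["mape"] == 0.0
        assert payload["pearson_r"] == pytest.approx(1.0)

    def test_disjoint_ids_join_failure(self, tmp_path):
        t = tmp_path / "t.tsv"
        e = tmp_path / "e.tsv"
        t.write_text("id\tcount\na\t10\nb\t20\nc\t30\n")
        e.write_text("id\tcount\nx\t10\ny\t20\nz\t30\n")
        res = CliRunner().invoke(cli_main, ["evaluate", str(t), str(e)])
        assert res.exit_code == fc.JoinFailure.exit_code

    def test_cli_report_matches_module_calls(self, tmp_path, rng):
        refs = rng.integers(20, 300, size=12)
        ests = refs + rng.integers(-4, 5, size=12)
        t = tmp_path / "t.tsv"
        e = tmp_path / "e.tsv"
        t.write_text("id\tcount\n" + "\n".join(f"v{i}\t{r}" for i, r in enumerate(refs)) + "\n")
        e.write_text("id\tcount\n" + "\n".join(f"v{i}\t{x}" for i, x in enumerate(ests)) + "\n")
        res = CliRunner().invoke(cli_main, ["evaluate", str(t), str(e), "--json"])
        payload = json.loads(res.output)
        pairs = [(int(r), int(x)) for r, x in zip(refs, ests)]
        assert payload["mae"] == pytest.approx(fc.mae(pairs), rel=1e-12)
        assert payload["mape"] == pytest.approx(fc.mape(pairs), rel=1e-12)
        assert payload["pearson_r"] == pytest.approx(fc.pearson_r(pairs)[0], rel=1e-12)
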