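"""Training schedule, orchestration contracts, file-level evaluation, CLI."""

import json

import numpy as np
import pytest
from click.testing import CliRunner

from tomatodet.cli import main as cli_main
from tomatodet.harness import (
    TrainConfig,
    detect,
    evaluate_cmd,
    load_split,
    lr_at_epoch,
    train,
)
from tomatodet.losses import compute_losses
from tomatodet.network import NetworkConfig, build_network
from tomatodet.nn import Adam, Tensor
from tomatodet.synthdata import SceneConfig, generate_dataset, generate_scene, write_annotations
from tomatodet.targets import encode
from tomatodet.harness import _normalize


class TestLrSchedule:
    def test_initial_rate(self):
        assert lr_at_epoch(0, TrainConfig()) == pytest.approx(1.25e-4)

    def test_after_first_drop(self):
        assert lr_at_epoch(100, TrainConfig()) == pytest.approx(1.25e-5)

    def test_after_second_drop(self):
        assert lr_at_epoch(130, TrainConfig()) == pytest.approx(1.25e-6)

    def test_boundary_epochs_inclusive(self):
        cfg = TrainConfig()
        assert lr_at_epoch(90, cfg) == pytest.approx(1.25e-5)
        assert lr_at_epoch(89, cfg) == pytest.approx(1.25e-4)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            lr_at_epoch(140, TrainConfig())
        with pytest.raises(ValueError):
            lr_at_epoch(-1, TrainConfig())

    def test_unsorted_drops_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(lr_drop_epochs=[120, 90])


def test_overfit_single_image_drops_loss_tenfold():
    """200 Adam steps on one scene shrink the composite loss >= 10x —
    the forward/backward path can fit the data it is shown."""
    scene = generate_scene(SceneConfig(seed=33, n_fruits=(2, 2)))
    h, w = scene.image.shape[:2]
    maps = encode(scene.circles, (w, h), stride=4)
    x = _normalize(scene.image)[None]
    net = build_network(NetworkConfig(preset="tiny", seed=0))
    opt = Adam(net.parameters(), lr=2e-3, clip_norm=5.0)
    initial = None
    for step in range(200):
        y, o, r = net(Tensor(x))
        total, _ = compute_losses(
            y, o, r, maps.heatmap, maps.offsets.astype(np.float32),
            maps.radii.astype(np.float32), maps.keypoint_mask,
        )
        if initial is None:
            initial = total.item()
        net.zero_grad()
        total.backward()
        opt.step()
    assert total.item() < initial / 10.0


@pytest.fixture(scope="module")
def small_samples():
    return [generate_scene(SceneConfig(seed=400 + i)) for i in range(10)]


@pytest.fixture(scope="module")
def model():
    return build_network(NetworkConfig(preset="tiny", seed=6))


class TestTrainLoop:
    def test_seeded_runs_identical(self, small_samples):
        cfg = TrainConfig.desk_scale(seed=3, epochs=2)
        _, log_a = train(cfg, list(small_samples), val_samples=[])
        _, log_b = train(cfg, list(small_samples), val_samples=[])
        assert [e["L_det"] for e in log_a] == [e["L_det"] for e in log_b]

    def test_log_lr_matches_schedule(self, small_samples):
        cfg = TrainConfig.desk_scale(seed=1, epochs=3)
        cfg.lr_drop_epochs = [2]
        _, log = train(cfg, list(small_samples), val_samples=[])
        assert [e["lr"] for e in log] == [lr_at_epoch(e["epoch"], cfg) for e in log]

    def test_checkpoints_and_log_written(self, small_samples, tmp_path):
        cfg = TrainConfig.desk_scale(seed=2, epochs=2)
        train(cfg, list(small_samples), out_dir=tmp_path)
        assert (tmp_path / "last.npz").is_file()
        assert (tmp_path / "best.npz").is_file()
        log = json.loads((tmp_path / "train_log.json").read_text())
        assert len(log) == 2 and "val_ap" in log[0]


class TestDetect:
    def test_detect_twice_identical(self, model):
        scene = generate_scene(SceneConfig(seed=77))
        a = detect(model, scene.image, score_threshold=0.0, n_max=10)
        b = detect(model, scene.image, score_threshold=0.0, n_max=10)
        assert [(c.cx, c.cy, c.r, c.score) for c in a.circles] == [
            (c.cx, c.cy, c.r, c.score) for c in b.circles
        ]

    def test_indivisible_input_padded_and_coords_in_original_frame(self, model):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 255, size=(61, 58, 3), dtype=np.uint8)
        dets = detect(model, img, score_threshold=0.0, n_max=50)
        assert dets.input_dims == (58, 61)
        for c in dets.circles:
            assert c.cx < 58 and c.cy < 61

    def test_box_head_decodes_equivalent_circles(self):
        model = build_network(NetworkConfig(preset="tiny", seed=6, head_type="box"))
        scene = generate_scene(SceneConfig(seed=78))
        dets = detect(model, scene.image, score_threshold=0.0, n_max=5)
        assert all(c.r > 0 for c in dets.circles)


class TestEvaluateCmd:
    def test_perfect_detection_files(self, tmp_path):
        gt_dir, det_dir = tmp_path / "gt", tmp_path / "det"
        gt_dir.mkdir(), det_dir.mkdir()
        for i in range(3):
            scene = generate_scene(SceneConfig(seed=500 + i))
            write_annotations(gt_dir / f"im{i}.txt", scene.circles)
            dets = [type(c)(c.cx, c.cy, c.r, score=0.9) for c in scene.circles]
            write_annotations(det_dir / f"im{i}.txt", dets, scores=True)
        report = evaluate_cmd(det_dir, gt_dir, report_path=tmp_path / "rep.json")
        assert report.recall == 100.0 and report.precision == 100.0
        assert (tmp_path / "rep.json").is_file()
        assert (tmp_path / "rep_pr.csv").is_file()

    def test_missing_detection_file_listed(self, tmp_path):
        gt_dir, det_dir = tmp_path / "gt", tmp_path / "det"
        gt_dir.mkdir(), det_dir.mkdir()
        write_annotations(gt_dir / "only.txt", [])
        with pytest.raises(FileNotFoundError, match="only"):
            evaluate_cmd(det_dir, gt_dir)


class TestCli:
    def test_synth_then_load_split(self, tmp_path):
        runner = CliRunner()
        res = runner.invoke(
            cli_main,
            ["synth", "--out-dir", str(tmp_path / "d"), "--n-train", "3",
             "--n-test", "2", "--seed", "5"],
        )
        assert res.exit_code == 0, res.output
        samples = load_split(tmp_path / "d", "train")
        assert len(samples) == 3

    def test_bad_counts_exit_code_2(self, tmp_path):
        runner = CliRunner()
        res = runner.invoke(
            cli_main, ["synth", "--out-dir", str(tmp_path), "--n-train", "-1"]
        )
        assert res.exit_code == 2

    def test_full_cli_pipeline_smoke(self, tmp_path):
        """synth -> train (1 epoch) -> detect -> eval produce a report."""
        runner = CliRunner()
        d = str(tmp_path / "data")
        assert runner.invoke(
            cli_main, ["synth", "--out-dir", d, "--n-train", "8", "--n-test", "2"]
        ).exit_code == 0
        run = str(tmp_path / "run")
        res = runner.invoke(
            cli_main, ["train", "--data-dir", d, "--out-dir", run, "--epochs", "1"]
        )
        assert res.exit_code == 0, res.output
        dets = str(tmp_path / "dets")
        res = runner.invoke(
            cli_main,
            ["detect", "--checkpoint", f"{run}/best.npz",
             "--image-dir", f"{d}/test/images", "--out-dir", dets,
             "--score-threshold", "0.05"],
        )
        assert res.exit_code == 0, res.output
        rep = str(tmp_path / "report.json")
        res = runner.invoke(
            cli_main,
            ["eval", "--det-dir", dets, "--gt-dir", f"{d}/test/labels",
             "--manifest", f"{d}/manifest.csv", "--report", rep],
        )
        assert res.exit_code == 0, res.output
        payload = json.loads((tmp_path / "report.json").read_text())
        assert {"precision_pct", "recall_pct", "ap_pct", "strata"} <= payload.keys()
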