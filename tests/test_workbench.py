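"""Config precedence, PNG round trips, checkpoint integrity, CLI smoke."""

import json

import numpy as np
import pytest
from click.testing import CliRunner

from ganseg.cli import main
from ganseg.phantoms import PhantomSpec, generate_phantom
from ganseg.training import TrainConfig, init_state, train
from ganseg.workbench import (load_checkpoint, load_config, read_image_pair,
                              save_checkpoint, write_image_pair)


class TestConfig:
    def test_desk_defaults(self):
        cfg = load_config(preset="desk")
        assert cfg.image_size == 64 and cfg.base_width == 8
        assert cfg.learning_rate == 0.01 and cfg.k == 6 and cfg.lam == 0.2
        assert cfg.batch_size == 10

    def test_paper_preset(self):
        cfg = load_config(preset="paper")
        assert cfg.image_size == 256 and cfg.base_width == 64
        assert cfg.epochs == 200

    def test_file_overrides_preset(self, tmp_path):
        f = tmp_path / "c.yaml"
        f.write_text("epochs: 5\n")
        cfg = load_config(f, preset="desk")
        assert cfg.epochs == 5
        assert cfg.base_width == 8  # everything else at preset defaults

    def test_cli_overrides_file(self, tmp_path):
        f = tmp_path / "c.yaml"
        f.write_text("epochs: 5\nseed: 3\n")
        cfg = load_config(f, overrides={"epochs": 9})
        assert cfg.epochs == 9 and cfg.seed == 3

    def test_unknown_key_named_in_error(self, tmp_path):
        f = tmp_path / "c.yaml"
        f.write_text("epcohs: 5\n")
        with pytest.raises(KeyError, match="epcohs"):
            load_config(f)

    def test_type_mismatch_rejected(self, tmp_path):
        f = tmp_path / "c.yaml"
        f.write_text("epochs: banana\n")
        with pytest.raises(TypeError, match="epochs"):
            load_config(f)

    def test_missing_file_rejected(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_config(tmp_path / "nope.yaml")


class TestCheckpoints:
    @pytest.fixture()
    def trained_state(self, tiny_configs, tiny_batch):
        gcfg, dcfg = tiny_configs
        imgs, labs = tiny_batch
        cfg = TrainConfig(seed=0, epochs=1, batch_size=2, k=1)
        return train(imgs, labs, cfg, gcfg, dcfg), imgs, labs

    def test_round_trip_bitwise(self, trained_state, tmp_path):
        st, _, _ = trained_state
        p = tmp_path / "ck.npz"
        save_checkpoint(st, p)
        st2 = load_checkpoint(p)
        for n, t in st.gen_params.items():
            np.testing.assert_array_equal(t.data, st2.gen_params[n].data)
        for n, t in st.disc_params.items():
            np.testing.assert_array_equal(t.data, st2.disc_params[n].data)
        for n, s in st.gen_state.items():
            np.testing.assert_array_equal(s["mean"], st2.gen_state[n]["mean"])
        assert st2.n_disc_updates == st.n_disc_updates
        assert st2.rng.bit_generator.state == st.rng.bit_generator.state

    def test_tampered_archive_rejected(self, trained_state, tmp_path):
        st, _, _ = trained_state
        p = tmp_path / "ck.npz"
        save_checkpoint(st, p)
        raw = bytearray(p.read_bytes())
        raw[len(raw) // 2] ^= 0xFF  # flip a bit in the array data region
        p.write_bytes(bytes(raw))
        with pytest.raises((ValueError, OSError)):
            load_checkpoint(p)

    def test_resume_equals_uninterrupted(self, tiny_configs, tiny_batch,
                                         tmp_path):
        """Two epochs straight == one epoch, checkpoint, resume one more."""
        gcfg, dcfg = tiny_configs
        imgs, labs = tiny_batch
        kw = dict(batch_size=2, k=2, deterministic=True)
        straight = train(imgs, labs, TrainConfig(seed=5, epochs=2, **kw),
                         gcfg, dcfg)
        half = train(imgs, labs, TrainConfig(seed=5, epochs=1, **kw),
                     gcfg, dcfg)
        p = tmp_path / "half.npz"
        save_checkpoint(half, p)
        resumed = load_checkpoint(p)
        resumed.cfg.epochs = 2
        train(imgs, labs, resumed.cfg, state=resumed)
        for n, t in straight.gen_params.items():
            np.testing.assert_array_equal(t.data, resumed.gen_params[n].data)
        for n, t in straight.disc_params.items():
            np.testing.assert_array_equal(t.data, resumed.disc_params[n].data)


class TestImageIO:
    def test_8bit_round_trip(self, tmp_path):
        s = generate_phantom(PhantomSpec(seed=2), 0)
        ip, lp = tmp_path / "i.png", tmp_path / "l.png"
        write_image_pair(s, ip, lp)
        back = read_image_pair(ip, lp)
        np.testing.assert_array_equal(back.label, s.label)
        assert np.abs(back.image - s.image).max() <= 1 / 255 + 1e-9

    def test_16bit_scaling(self, tmp_path):
        s = generate_phantom(PhantomSpec(seed=2), 1)
        ip, lp = tmp_path / "i.png", tmp_path / "l.png"
        write_image_pair(s, ip, lp, bits=16)
        back = read_image_pair(ip, lp)
        assert np.abs(back.image - s.image).max() <= 1 / 65535 + 1e-9

    def test_label_value_validation(self, tmp_path):
        s = generate_phantom(PhantomSpec(seed=2), 0)
        ip, lp = tmp_path / "i.png", tmp_path / "l.png"
        write_image_pair(s, ip, lp)
        with pytest.raises(ValueError, match="pixel"):
            read_image_pair(ip, lp, num_classes=2)

    def test_size_mismatch_rejected(self, tmp_path):
        s1 = generate_phantom(PhantomSpec(seed=2), 0)
        s2 = generate_phantom(PhantomSpec(image_size=32, seed=2), 0)
        write_image_pair(s1, tmp_path / "a.png", tmp_path / "al.png")
        write_image_pair(s2, tmp_path / "b.png", tmp_path / "bl.png")
        with pytest.raises(ValueError, match="differ"):
            read_image_pair(tmp_path / "a.png", tmp_path / "bl.png")


class TestCLI:
    def test_generate_and_evaluate_perfect_prediction(self, tmp_path):
        runner = CliRunner()
        res = runner.invoke(main, [
            "generate", "--preset", "desk", "--seed", "1",
            "--n-originals", "4", "--dataset-dir", str(tmp_path / "ds")])
        assert res.exit_code == 0, res.output
        assert (tmp_path / "ds" / "manifest.json").exists()
        truth = tmp_path / "ds" / "test"
        res = runner.invoke(main, [
            "evaluate", "--pred-dir", str(truth), "--truth-dir", str(truth)])
        assert res.exit_code == 0, res.output
        assert "1.0000" in res.output

    def test_train_zero_epochs_writes_init_checkpoint(self, tmp_path):
        runner = CliRunner()
        ds = tmp_path / "ds"
        runner.invoke(main, ["generate", "--seed", "2", "--n-originals", "4",
                             "--dataset-dir", str(ds)])
        res = runner.invoke(main, [
            "train", "--seed", "2", "--epochs", "0",
            "--dataset-dir", str(ds), "--output-dir", str(tmp_path / "out"),
            "--config", "/dev/null"] if False else [
            "train", "--seed", "2", "--epochs", "0",
            "--dataset-dir", str(ds), "--output-dir", str(tmp_path / "out")])
        assert res.exit_code == 0, res.output
        ck = tmp_path / "out" / "checkpoint_last.npz"
        assert ck.exists()
        st = load_checkpoint(ck)
        assert st.n_gen_updates == 0 and st.epoch == 0
        manifest = json.loads(
            (tmp_path / "out" / "run_manifest.json").read_text())
        assert manifest["seed"] == 2 and "config" in manifest
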