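"""Study configs and reproducible simulation grids."""

from __future__ import annotations

import pytest
import yaml

from seqtest import load_config, reproduce_grid, save_config
from seqtest.reporting import ConfigError, _cell_seed

MINIMAL = {
    "replicates": 50,
    "seed": 17,
    "delta_true": [0.0, 0.5],
    "designs": [
        {"label": "sprt-05", "test": "sprt", "delta1": 0.5,
         "alpha": 0.05, "beta": 0.1, "n_max": 100},
    ],
}


def write(tmp_path, doc, name="study.yaml"):
    p = tmp_path / name
    p.write_text(yaml.safe_dump(doc))
    return p


def test_minimal_config_fills_defaults(tmp_path):
    cfg = load_config(write(tmp_path, MINIMAL))
    assert cfg.replicates == 50 and cfg.seed == 17
    label, design = cfg.designs[0]
    assert label == "sprt-05"
    assert design.n_start == 2 and design.n_step == 1
    assert design.thresholds.upper == pytest.approx(18.0)


@pytest.mark.parametrize("mutate,match", [
    (lambda d: d["designs"][0].update(alpha=1.2), "alpha"),
    (lambda d: d["designs"][0].update(frobnicate=1), "frobnicate"),
    (lambda d: d.update(extra_key=1), "extra_key"),
    (lambda d: d["designs"][0].pop("delta1"), "delta1"),
    (lambda d: d["designs"][0].pop("alpha"), "alpha"),
    (lambda d: d.pop("designs"), "designs"),
    (lambda d: d.pop("delta_true"), "delta_true"),
    (lambda d: d.update(replicates=0), "replicates"),
    (lambda d: d["designs"][0].update(test="anova"), "test"),
    (lambda d: d["designs"][0].update(log_lower=-1.0), "log_upper"),
])
def test_schema_violations_rejected(tmp_path, mutate, match):
    import copy
    doc = copy.deepcopy(MINIMAL)
    mutate(doc)
    with pytest.raises(ConfigError, match=match):
        load_config(write(tmp_path, doc))


def test_duplicate_labels_rejected(tmp_path):
    import copy
    doc = copy.deepcopy(MINIMAL)
    doc["designs"].append(dict(doc["designs"][0]))
    with pytest.raises(ConfigError, match="unique"):
        load_config(write(tmp_path, doc))


def test_sbft_config_and_roundtrip(tmp_path):
    doc = {
        "replicates": 20, "seed": 3, "delta_true": [0.4],
        "designs": [
            {"label": "bf", "test": "sbft", "sided": 1,
             "prior": {"family": "cauchy", "scale": 0.7071067811865476,
                       "truncation": "positive"},
             "log_lower": -2.25, "log_upper": 2.89, "n_max": 60},
            {"label": "lr", "test": "sprt", "delta1": 0.4, "delta0": 0.1,
             "alpha": 0.05, "beta": 0.1, "n_max": 60},
        ],
    }
    cfg = load_config(write(tmp_path, doc))
    out = tmp_path / "roundtrip.yaml"
    save_config(cfg, out)
    cfg2 = load_config(out)
    assert cfg2.designs == cfg.designs
    assert cfg2.delta_true == cfg.delta_true
    assert cfg2.replicates == cfg.replicates and cfg2.seed == cfg.seed


def test_cell_seeds_depend_on_position_not_order():
    a = _cell_seed(5, 1, 2)
    b = _cell_seed(5, 1, 2)
    c = _cell_seed(5, 2, 1)
    assert a.generate_state(2).tolist() == b.generate_state(2).tolist()
    assert a.generate_state(2).tolist() != c.generate_state(2).tolist()


def test_smoke_grid_runs_and_reruns_identically(tmp_path):
    cfg = load_config(write(tmp_path, MINIMAL))
    out1, out2 = tmp_path / "a.csv", tmp_path / "b.csv"
    table = reproduce_grid(cfg, out_path=out1)
    assert len(table) == 2
    assert set(table["label"]) == {"sprt-05"}
    assert (table["seed"] == 17).all()
    assert table["n_replicates"].eq(50).all()
    reproduce_grid(cfg, out_path=out2)
    assert out1.read_bytes() == out2.read_bytes()
    assert not (tmp_path / "a.csv.resume.json").exists()
    # config sidecar documents what produced the CSV
    import json
    sidecar = json.loads((tmp_path / "a.csv.config.json").read_text())
    assert sidecar["seed"] == 17 and sidecar["replicates"] == 50
    assert sidecar["designs"][0]["label"] == "sprt-05"


def test_grid_resume_reuses_completed_cells(tmp_path, monkeypatch):
    import seqtest.reporting as rep

    cfg = load_config(write(tmp_path, MINIMAL))
    ref = tmp_path / "ref.csv"
    reproduce_grid(cfg, out_path=ref)

    out = tmp_path / "partial.csv"
    calls = {"n": 0}
    orig = rep.simulate_design

    def boom(*args, **kwargs):
        calls["n"] += 1
        if calls["n"] == 2:
            raise KeyboardInterrupt
        return orig(*args, **kwargs)

    monkeypatch.setattr(rep, "simulate_design", boom)
    with pytest.raises(KeyboardInterrupt):
        reproduce_grid(cfg, out_path=out)
    assert out.with_suffix(".csv.resume.json").exists()
    monkeypatch.setattr(rep, "simulate_design", orig)
    reproduce_grid(cfg, out_path=out, resume=True)
    assert out.read_bytes() == ref.read_bytes()
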