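"""I/O round-trips, pipeline contracts, combination study, leakage audit."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from freshnir import (
    GeneratorConfig,
    PipelineConfig,
    PreprocessSpec,
    generate_dataset,
    read_reference_csv,
    read_spectra_csv,
    run_combination_study,
    run_pipeline,
    write_reference_csv,
    write_spectra_csv,
)
from freshnir.synthetic_data import noiseless
from freshnir.workbench import combination_grid, fit_and_evaluate


def small_config(**overrides):
    gen = GeneratorConfig(seed=5, n_samples_per_group_day=1, n_channels=120,
                          wavelength_step_nm=1920.0 / 119)
    base = dict(
        target="tvbn", generator=gen,
        preprocess=PreprocessSpec(method="snv"),
        selector="spa", model="pls", seed=5,
    )
    base.update(overrides)
    return PipelineConfig(**base)


class TestCsvRoundTrip:
    def test_spectra_round_trip_bit_exact(self, tmp_path, small_dataset):
        spectra, _, _ = small_dataset
        path = tmp_path / "spectra.csv"
        write_spectra_csv(spectra, path)
        back = read_spectra_csv(path)
        np.testing.assert_array_equal(back.absorbance, spectra.absorbance)
        np.testing.assert_array_equal(back.wavelengths_nm, spectra.wavelengths_nm)
        assert list(back.sample_ids) == list(spectra.sample_ids)
        assert list(back.metadata.group) == list(spectra.metadata.group)

    def test_reference_round_trip(self, tmp_path, small_dataset):
        spectra, reference, _ = small_dataset
        path = tmp_path / "reference.csv"
        write_reference_csv(reference, path, spectra.metadata)
        back = read_reference_csv(path)
        pd.testing.assert_frame_equal(back.table, reference.table)

    def test_decreasing_wavelength_header_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("sample_id,800.0,700.0\ns0,0.1,0.2\n")
        with pytest.raises(ValueError, match="strictly increasing"):
            read_spectra_csv(path)

    def test_missing_cell_names_sample_and_wavelength(self, tmp_path):
        path = tmp_path / "gap.csv"
        path.write_text("sample_id,700.0,710.0\ns0,0.1,\ns1,0.2,0.3\n")
        with pytest.raises(ValueError, match="s0.*710"):
            read_spectra_csv(path)


class TestPipeline:
    def test_smoke_run_produces_full_record(self, tmp_path):
        cfg = small_config(out_dir=str(tmp_path / "run"))
        rec = run_pipeline(cfg)
        ev = rec.evaluation
        assert ev is not None and ev.rmse_test >= 0
        assert rec.subset is not None and rec.subset.n_selected >= 1
        assert (tmp_path / "run" / "evaluation.json").exists()
        assert (tmp_path / "run" / "run_record.json").exists()
        # split respects the 7:3 convention within one sample
        n = len(rec.train_ids) + len(rec.test_ids)
        assert abs(len(rec.train_ids) - 0.7 * n) <= 1

    def test_selector_none_uses_full_spectrum(self):
        rec = run_pipeline(small_config(selector="none", screen=False))
        assert rec.subset is None
        assert rec.evaluation.n_channels_used == 120

    def test_rerun_from_config_is_identical(self):
        cfg = small_config(screen=False)
        a = run_pipeline(cfg)
        b = run_pipeline(cfg)
        assert a.evaluation.to_dict() == b.evaluation.to_dict()
        assert a.train_ids == b.train_ids

    def test_config_dict_round_trip_preserves_run(self):
        cfg = small_config(screen=False)
        clone = PipelineConfig.from_dict(cfg.to_dict())
        assert run_pipeline(clone).evaluation.to_dict() == \
            run_pipeline(cfg).evaluation.to_dict()

    def test_invalid_source_combination_rejected(self):
        with pytest.raises(ValueError, match="exactly one input source"):
            PipelineConfig(target="tvbn")


class TestLeakage:
    def test_corrupting_test_targets_changes_only_prediction_metrics(self):
        """Post-split stages never read y_test before evaluation."""
        cfg = small_config(screen=False)
        spectra, reference, _ = generate_dataset(cfg.generator)
        from freshnir.preprocessing import fit_preprocessor
        from freshnir.sample_split import spxy_split

        t = fit_preprocessor(cfg.preprocess, spectra).transform(spectra)
        y = reference.values_for("tvbn", t.sample_ids)
        split = spxy_split(t.absorbance, y, 0.7)
        tr = np.asarray(split.train_indices)
        te = np.asarray(split.test_indices)
        X_tr, X_te = t.absorbance[tr], t.absorbance[te]

        _, _, clean = fit_and_evaluate(cfg, X_tr, y[tr], X_te, y[te],
                                       t.wavelengths_nm)
        y_bad = y[te] + 5.0 * np.random.default_rng(1).normal(size=te.size)
        _, _, dirty = fit_and_evaluate(cfg, X_tr, y[tr], X_te, y_bad,
                                       t.wavelengths_nm)
        assert dirty.r2_train == clean.r2_train
        assert dirty.rmse_train == clean.rmse_train
        assert dirty.lod == clean.lod
        assert dirty.r2_test != clean.r2_test


class TestCombinationStudy:
    def test_grid_produces_one_row_per_cell(self):
        base = small_config(screen=False)
        cells = combination_grid(base, ["snv", "norm"], ["none", "spa"], ["pls"])
        table = run_combination_study(cells)
        assert len(table) == 4
        assert table.error.isna().all()
        assert set(table.selector) == {"none", "spa"}

    def test_noiseless_cells_all_reach_high_prediction_accuracy(self):
        """Without noise the spectra are affine in the indicators, so any
        linear-operator preprocessing + PLS predicts almost perfectly."""
        gen = noiseless(GeneratorConfig(
            seed=5, n_samples_per_group_day=1, n_channels=120,
            wavelength_step_nm=1920.0 / 119,
        ))
        base = small_config(generator=gen, screen=False)
        cells = combination_grid(base, ["none", "sg"], ["none", "spa"], ["pls"])
        table = run_combination_study(cells)
        assert (table.R2p >= 0.99).all()

    def test_common_seed_shares_the_random_split(self):
        base = small_config(screen=False, split_method="random")
        a = run_pipeline(replace(base, selector="none"))
        b = run_pipeline(replace(base, selector="spa"))
        assert a.train_ids == b.train_ids
        assert a.test_ids == b.test_ids

    def test_cell_failure_recorded_not_raised(self):
        base = small_config(screen=False)
        # a 1-sample prediction set has zero target variance, so R²p is
        # undefined and that cell must fail -- without killing the study
        broken = replace(base, split_ratio=0.999)
        table = run_combination_study([base, broken])
        assert pd.isna(table.error.iloc[0])
        assert isinstance(table.error.iloc[1], str)
        assert pd.notna(table.R2p.iloc[0])
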