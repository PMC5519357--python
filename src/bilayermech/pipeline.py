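"""End-to-end analysis: area series + z-table → K_A, d, κ, report.

This is the library face of the ``analyze`` command; the CLI is a thin
wrapper around :func:`analyze_config`.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

from . import io, units
from .area import apply_equilibration_cut, estimate_area_modulus
from .config import LipidSection, RunConfig
from .rigidity import ElasticityResult, comparative_report, compute_bending_rigidity
from .synthetic import generate_area_series, generate_phosphorus_z
from .thickness import build_density_profile, peak_to_peak_thickness

logger = logging.getLogger("bilayermech")


def analyze_section(
    section: LipidSection,
    d0_nm: float,
    bin_width_nm: float,
    equilibration: int | float,
) -> ElasticityResult:
    """Run the full pipeline for one lipid/temperature condition."""
    if section.synthetic is not None:
        series = generate_area_series(section.synthetic)
        z_table = generate_phosphorus_z(section.synthetic)
    else:
        series = io.read_area_table(section.area_file, section.temperature)
        z_table = io.read_z_table(section.z_file)

    cut = section.equilibration if section.equilibration is not None else equilibration
    series = apply_equilibration_cut(series, cut)
    modulus = estimate_area_modulus(series, stride=section.stride)
    profile = build_density_profile(z_table, bin_width=bin_width_nm)
    d = peak_to_peak_thickness(profile)
    result = compute_bending_rigidity(
        area_modulus=modulus.value_mn_per_m,
        area_modulus_se=modulus.se_mn_per_m,
        thickness=d.value_nm,
        thickness_se=d.se_nm,
        d0=d0_nm,
        temperature=section.temperature,
        lipid_label=section.label,
    )
    logger.info(
        "%s @ %.2f K: kB=%.6e J/K, cut=%d frames, plateau block=%d, "
        "K_A=%.2f±%.2f mN/m, d=%.3f±%.3f nm, kappa=%.2f kBT",
        section.label,
        section.temperature,
        units.KB,
        series.equilibration_cut,
        modulus.block_curve.plateau_block,
        modulus.value_mn_per_m,
        modulus.se_mn_per_m,
        d.value_nm,
        d.se_nm,
        result.kappa_kbt,
    )
    return result


def analyze_config(config: RunConfig, write_outputs: bool = True) -> dict:
    """Analyze every section of a run config and build the comparative report.

    Writes ``report.json`` and ``report.csv`` under the config's output
    directory (plus a log recording the config hash) unless
    ``write_outputs`` is False.  Returns the report dict.
    """
    results = [
        analyze_section(s, config.d0_nm, config.bin_width_nm, config.equilibration)
        for s in config.sections
    ]
    report = comparative_report(results)
    if write_outputs:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        io.write_json(report, outdir / "report.json")
        from .rigidity import report_table

        report_table(report).to_csv(outdir / "report.csv", index=False)
        if config.config_path is not None:
            digest = hashlib.sha256(config.config_path.read_bytes()).hexdigest()
            logger.info("config %s sha256=%s", config.config_path, digest)
            (outdir / "run.log").write_text(
                f"config_sha256={digest}\nkB_J_per_K={units.KB!r}\n"
                f"d0_nm={config.d0_nm}\nbin_width_nm={config.bin_width_nm}\n"
                f"equilibration={config.equilibration}\n"
            )
    return report
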