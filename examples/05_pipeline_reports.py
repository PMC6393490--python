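"""Config-driven report generation, end to end, in a temp directory.

Writes synthetic structures, a register file and an ensemble to disk,
builds a YAML analysis config, and runs the geometry / comparison /
flexibility reports the same way the CLI does.
"""

import tempfile
from pathlib import Path

import numpy as np
import yaml

from coilkit import (AnalysisConfig, CrickParams, StutterSpec,
                     build_crick_dimer, perturb_ensemble,
                     run_comparison_report, run_flexibility_report,
                     run_geometry_report, serialize_register,
                     write_ensemble, write_structure)

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    bf = 20.0 + 10.0 * np.abs(np.linspace(-1.0, 1.0, 117))
    ideal, assign = build_crick_dimer(CrickParams(), bfactors=bf)
    stuttered, _ = build_crick_dimer(CrickParams(),
                                     StutterSpec(insert_after=56),
                                     bfactors=bf)
    write_structure(ideal, tmp / "ideal.pdb")
    write_structure(stuttered, tmp / "stutter.pdb")
    (tmp / "register.txt").write_text(serialize_register(assign) + "\n")
    write_ensemble(perturb_ensemble(ideal, 0.3, 10, seed=1),
                   tmp / "ensemble.pdb")

    config = {
        "structures": [
            {"path": str(tmp / "ideal.pdb"), "label": "ideal",
             "chains": ["A", "B"]},
            {"path": str(tmp / "stutter.pdb"), "label": "stutter",
             "chains": ["A", "B"]},
        ],
        "regions": [
            {"label": "pre_insert", "ranges": [[1, 50]],
             "atom_class": "calpha"},
            {"label": "full", "ranges": [[1, 117]], "atom_class": "calpha"},
        ],
        "register_path": str(tmp / "register.txt"),
        "ensemble_path": str(tmp / "ensemble.pdb"),
        "out_dir": str(tmp / "reports"),
    }
    (tmp / "config.yaml").write_text(yaml.safe_dump(config))

    cfg = AnalysisConfig.from_yaml(tmp / "config.yaml")
    for label, path in run_geometry_report(cfg).items():
        print(f"geometry    {label}: {path.name}")
    print(f"comparison  {run_comparison_report(cfg).name}")
    for label, path in run_flexibility_report(cfg).items():
        print(f"flexibility {label}: {path.name}")

    print("\ncomparison.tsv:")
    print((tmp / "reports" / "comparison.tsv").read_text())
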