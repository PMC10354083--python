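"""Apply the checklist inclusion filters and extract buffer-median radiance.

Reads the world written by 01_simulate_world.py, applies the standard
rules (complete only, allowed protocols, <= 300 min, <= 5 km, 2010-01-01
to 2021-06-30), reports the removals per rule, and attaches the 5-km
buffer-median radiance and hex-cell assignment to every surviving
checklist.  Outputs: results/filter_report.json, results/checklists_prepared.csv.
"""

import json

from common import RESULTS, WORLD_DIR

import urbantol as ut


def main() -> None:
    checklists, obs = ut.read_checklists(WORLD_DIR / "checklists.tsv")
    print(f"read {len(checklists)} checklists, {len(obs)} observation rows")

    survivors, report = ut.filter_checklists(checklists)
    print("removals per rule:", {k: v for k, v in report.removed.items() if v})
    print(f"{report.n_retained}/{report.n_input} checklists retained")
    (RESULTS / "filter_report.json").write_text(report.to_json())

    raster = ut.RadianceRaster.read_text(WORLD_DIR / "alan.grid")
    grid = ut.HexGrid(5.0)
    prepared = ut.prepare_covariates(survivors, raster, grid, buffer_radius_km=5.0)
    print(f"radiance at checklists: median {prepared['x_alan'].median():.3f}, "
          f"brightest {prepared['x_alan'].max():.3f}, "
          f"darkest {prepared['x_alan'].min():.3f} nW cm-2 sr-1")
    print(f"{prepared[['cell_q', 'cell_r']].drop_duplicates().shape[0]} occupied "
          f"5-km hex cells")
    prepared.to_csv(RESULTS / "checklists_prepared.csv", index=False)
    print(f"wrote {RESULTS / 'checklists_prepared.csv'}")


if __name__ == "__main__":
    main()
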