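"""Export of fields, cell censuses, vessel networks and reports.

Fields are written as ASCII VTK XML ImageData (``.vti``) or flat CSV
(x, y, z, value); vessel networks as VTK PolyData polylines (``.vtp``) with
per-segment attributes, or as a CSV edge list.  The writers emit the plain
ASCII flavour of the VTK XML formats, which ParaView and VisIt read
directly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .grid import ScalarField
from .tumor_cells import PHENOTYPE_NAMES, CellPopulation


def write_vti(fields: list[ScalarField] | ScalarField, path) -> None:
    """Write one or more same-lattice scalar fields as ASCII .vti ImageData."""
    if isinstance(fields, ScalarField):
        fields = [fields]
    lat = fields[0].lattice
    nx, ny, nz = lat.shape
    ox, oy, oz = lat.origin
    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="ImageData" version="0.1" byte_order="LittleEndian">',
        f'  <ImageData WholeExtent="0 {nx - 1} 0 {ny - 1} 0 {nz - 1}"'
        f' Origin="{ox} {oy} {oz}" Spacing="{lat.h} {lat.h} {lat.h}">',
        f'    <Piece Extent="0 {nx - 1} 0 {ny - 1} 0 {nz - 1}">',
        "      <PointData>",
    ]
    for f in fields:
        # VTK ImageData iterates x fastest: transpose to z, y, x order
        flat = np.asarray(f.values).transpose(2, 1, 0).ravel()
        data = " ".join(f"{v:.8g}" for v in flat)
        lines.append(
            f'        <DataArray type="Float64" Name="{f.name}" format="ascii">'
        )
        lines.append("          " + data)
        lines.append("        </DataArray>")
    lines += [
        "      </PointData>",
        "    </Piece>",
        "  </ImageData>",
        "</VTKFile>",
    ]
    Path(path).write_text("\n".join(lines))


def field_to_csv(f: ScalarField, path) -> None:
    lat = f.lattice
    idx = np.indices(lat.shape).reshape(3, -1).T
    coords = np.asarray(lat.origin) + lat.h * idx
    df = pd.DataFrame(
        {"x": coords[:, 0], "y": coords[:, 1], "z": coords[:, 2],
         "value": f.values.ravel()}
    )
    df.to_csv(path, index=False)


_EDGE_ATTRS = ("d_v", "d_v_def", "H_D", "Q_lum", "tau", "L", "kind")


def network_to_csv(network, path) -> None:
    """Edge list with endpoint coordinates (um) and per-segment attributes."""
    lat = network.lattice
    rows = []
    for a, b, d in network.graph.edges(data=True):
        ca, cb = lat.coords(a), lat.coords(b)
        row = {
            "x0": ca[0], "y0": ca[1], "z0": ca[2],
            "x1": cb[0], "y1": cb[1], "z1": cb[2],
        }
        row.update({k: d.get(k) for k in _EDGE_ATTRS})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_vtp(network, path) -> None:
    """Vessel network as ASCII .vtp polylines with per-segment attributes."""
    lat = network.lattice
    nodes = list(network.graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    pts = " ".join(
        " ".join(f"{c:.6g}" for c in lat.coords(n)) for n in nodes
    )
    edges = list(network.graph.edges(data=True))
    conn = " ".join(f"{index[a]} {index[b]}" for a, b, _ in edges)
    offs = " ".join(str(2 * (i + 1)) for i in range(len(edges)))
    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="PolyData" version="0.1" byte_order="LittleEndian">',
        "  <PolyData>",
        f'    <Piece NumberOfPoints="{len(nodes)}" NumberOfLines="{len(edges)}">',
        "      <Points>",
        '        <DataArray type="Float64" NumberOfComponents="3" format="ascii">',
        "          " + pts,
        "        </DataArray>",
        "      </Points>",
        "      <Lines>",
        '        <DataArray type="Int64" Name="connectivity" format="ascii">',
        "          " + conn,
        "        </DataArray>",
        '        <DataArray type="Int64" Name="offsets" format="ascii">',
        "          " + offs,
        "        </DataArray>",
        "      </Lines>",
        "      <CellData>",
    ]
    for attr in ("d_v", "d_v_def", "H_D", "Q_lum", "tau"):
        vals = " ".join(f"{d.get(attr, 0.0):.8g}" for *_, d in edges)
        lines.append(
            f'        <DataArray type="Float64" Name="{attr}" format="ascii">'
        )
        lines.append("          " + vals)
        lines.append("        </DataArray>")
    lines += [
        "      </CellData>",
        "    </Piece>",
        "  </PolyData>",
        "</VTKFile>",
    ]
    Path(path).write_text("\n".join(lines))


def cells_to_csv(population: CellPopulation, path) -> None:
    rows = [
        {
            "i": int(c.site[0]), "j": int(c.site[1]), "k": int(c.site[2]),
            "phenotype": PHENOTYPE_NAMES[c.phenotype], "psi": c.psi, "age_s": c.age,
        }
        for c in population.cells()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_run_outputs(state, outdir: Path) -> None:
    """Standard output bundle for one finished run."""
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    state.report.to_tidy_csv(outdir / "metrics.csv")
    summary = {
        "events": state.report.events,
        "parameter_digest": state.report.parameter_digest,
        "final": state.report.final(),
        "clamp_audit": state.clamp_audit.total_clamped,
        "scenario": state.config.scenario.label,
        "seed": state.config.seed,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    cells_to_csv(state.population, outdir / "cells.csv")
    network_to_csv(state.network, outdir / "network.csv")
    write_vtp(state.network, outdir / "network.vtp")
    write_vti(
        [state.fields[n] for n in ("c_o2", "c_g", "c_co2", "c_v")] + [state.p_ins],
        outdir / "fields.vti",
    )
    from .simulation import save_checkpoint

    save_checkpoint(state, outdir / "checkpoint.pkl")
    cfg_echo = {
        "name": state.config.name,
        "seed": state.config.seed,
        "t_end_days": state.config.t_end_days,
        "lattice": [*state.config.lattice.shape, state.config.lattice.h],
        "scenario": state.config.scenario.label,
        "parameters": state.params.to_dict(),
    }
    (outdir / "config_echo.json").write_text(json.dumps(cfg_echo, indent=2))
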