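"""Plain-text coordinate/trajectory I/O in a GRO-dialect format.

Frames are concatenated GRO records: title line (carries the time),
atom count, one fixed-width line per site (residue index/name, atom
name, atom index, x y z in nm, vx vy vz in nm/ps), and the box line.
"""

from __future__ import annotations

import numpy as np

from .core import SystemState, Topology, build_topology
from .forcefield import ForceField
from .trajectory import Trajectory


def _format_frame(title: str, top: Topology, positions: np.ndarray,
                  velocities: np.ndarray | None, box: np.ndarray) -> str:
    lines = [title, f"{top.n_sites:5d}"]
    site_in_mol = np.zeros(top.n_sites, dtype=int)
    for m in range(top.n_molecules):
        f = top.first_site[m]
        site_in_mol[f:f + top.sites_per_molecule[m]] = np.arange(
            top.sites_per_molecule[m])
    for i in range(top.n_sites):
        mol = top.site_molecule[i]
        res = mol + 1
        resname = top.species_names[top.molecule_species[mol]]
        # site names by species definition order are not stored in the
        # topology; use the species name + in-molecule site index
        atname = f"{resname}{site_in_mol[i] + 1}"
        x, y, z = positions[i]
        if velocities is not None:
            vx, vy, vz = velocities[i]
            lines.append(f"{res % 100000:5d}{resname:<5s}{atname:>5s}"
                         f"{(i + 1) % 100000:5d}"
                         f"{x:8.3f}{y:8.3f}{z:8.3f}"
                         f"{vx:8.4f}{vy:8.4f}{vz:8.4f}")
        else:
            lines.append(f"{res % 100000:5d}{resname:<5s}{atname:>5s}"
                         f"{(i + 1) % 100000:5d}"
                         f"{x:8.3f}{y:8.3f}{z:8.3f}")
    lines.append(f"{box[0]:10.5f}{box[1]:10.5f}{box[2]:10.5f}")
    return "\n".join(lines) + "\n"


def write_state(path, state: SystemState, title: str = "mtslab") -> None:
    with open(path, "w") as fh:
        fh.write(_format_frame(f"{title} t= {state.time:.4f} ps",
                               state.topology, state.positions,
                               state.velocities, state.box))


def write_trajectory(path, traj: Trajectory, title: str = "mtslab") -> None:
    with open(path, "w") as fh:
        for k in range(traj.n_frames):
            fh.write(_format_frame(f"{title} t= {traj.times[k]:.4f} ps",
                                   traj.topology, traj.positions[k], None,
                                   traj.boxes[k]))


def _parse_frames(path):
    with open(path) as fh:
        lines = fh.read().splitlines()
    k = 0
    while k < len(lines):
        title = lines[k]
        n = int(lines[k + 1])
        body = lines[k + 2:k + 2 + n]
        box = np.array([float(v) for v in lines[k + 2 + n].split()[:3]])
        time = 0.0
        if "t=" in title:
            time = float(title.split("t=")[1].split()[0])
        yield title, time, body, box
        k += n + 3


def _parse_body(body: list[str]):
    res_names = []
    pos = np.empty((len(body), 3))
    vel = np.zeros((len(body), 3))
    res_ids = np.empty(len(body), dtype=int)
    for i, line in enumerate(body):
        res_ids[i] = int(line[0:5])
        res_names.append(line[5:10].strip())
        pos[i] = [float(line[20:28]), float(line[28:36]),
                  float(line[36:44])]
        if len(line) >= 68:
            vel[i] = [float(line[44:52]), float(line[52:60]),
                      float(line[60:68])]
    return res_ids, res_names, pos, vel


def _topology_from_frame(res_ids, res_names, ff: ForceField) -> Topology:
    blocks: list[tuple[str, int]] = []
    prev = None
    for i in range(len(res_ids)):
        key = (res_ids[i], res_names[i])
        if key != prev:
            name = res_names[i]
            if blocks and blocks[-1][0] == name:
                blocks[-1] = (name, blocks[-1][1] + 1)
            else:
                blocks.append((name, 1))
            prev = key
    return build_topology(ff, blocks)


def read_state(path, ff: ForceField) -> SystemState:
    """Read the first frame of a GRO-dialect file as a SystemState."""
    _, time, body, box = next(_parse_frames(path))
    res_ids, res_names, pos, vel = _parse_body(body)
    top = _topology_from_frame(res_ids, res_names, ff)
    return SystemState(positions=pos, velocities=vel, box=box,
                       topology=top, time=time)


def read_trajectory(path, ff: ForceField) -> Trajectory:
    traj = None
    for _, time, body, box in _parse_frames(path):
        res_ids, res_names, pos, _ = _parse_body(body)
        if traj is None:
            traj = Trajectory(_topology_from_frame(res_ids, res_names, ff))
        traj.append(time, pos, box)
    if traj is None:
        raise ValueError(f"no frames found in {path}")
    return traj
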