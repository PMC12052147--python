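"""Plain-text and HDF5 serialization helpers."""

from __future__ import annotations

import json

import numpy as np

from .spike_models import SpikeTrainSet

__all__ = ["write_spike_trains", "read_spike_trains",
           "write_spike_trains_npz", "read_spike_trains_npz",
           "write_signals", "read_signals",
           "write_currents", "read_currents"]


def write_spike_trains(path, spikes: SpikeTrainSet):
    """Two-column text (train_id, spike_time_ms) with a metadata header."""
    with open(path, "w") as fh:
        meta = {"duration": spikes.duration, "n_trains": spikes.n_trains,
                **spikes.provenance}
        fh.write(f"# popkernel-spikes {json.dumps(meta)}\n")
        fh.write("# train_id\tspike_time_ms\n")
        for i, train in enumerate(spikes.trains):
            for t in train:
                fh.write(f"{i}\t{t:.6f}\n")


def read_spike_trains(path) -> SpikeTrainSet:
    meta = {}
    ids, times = [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("# popkernel-spikes"):
                meta = json.loads(line.split(None, 2)[2])
            elif line.startswith("#") or not line.strip():
                continue
            else:
                i, t = line.split()
                ids.append(int(i))
                times.append(float(t))
    n = int(meta.pop("n_trains"))
    duration = float(meta.pop("duration"))
    ids = np.asarray(ids)
    times = np.asarray(times)
    trains = [np.sort(times[ids == i]) for i in range(n)]
    return SpikeTrainSet(trains, duration, provenance=meta)


def write_spike_trains_npz(path, spikes: SpikeTrainSet):
    """Packed binary container: concatenated times + train offsets."""
    times = (np.concatenate(spikes.trains) if spikes.trains
             else np.array([]))
    offsets = np.cumsum([0] + [t.size for t in spikes.trains])
    np.savez_compressed(path, times=times, offsets=offsets,
                        duration=spikes.duration,
                        provenance=json.dumps(spikes.provenance))


def read_spike_trains_npz(path) -> SpikeTrainSet:
    with np.load(path, allow_pickle=False) as fh:
        times = fh["times"]
        offsets = fh["offsets"]
        duration = float(fh["duration"])
        provenance = json.loads(str(fh["provenance"]))
    trains = [times[offsets[i]:offsets[i + 1]]
              for i in range(offsets.size - 1)]
    return SpikeTrainSet(trains, duration, provenance=provenance)


def write_currents(path, field, positions=None):
    """Membrane-current container (HDF5) with dt and optional positions."""
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("currents", data=field.currents)
        fh.attrs["dt"] = field.dt
        fh.attrs["units"] = "nA"
        if positions is not None:
            fh.create_dataset("positions", data=np.asarray(positions))


def read_currents(path):
    import h5py

    from .forward_model import MembraneCurrentField

    with h5py.File(path, "r") as fh:
        return MembraneCurrentField(fh["currents"][()],
                                    float(fh.attrs["dt"]))


def write_signals(path, signal):
    """Signal container (HDF5) with dt/units/label attributes."""
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("traces", data=signal.traces)
        fh.attrs["dt"] = signal.dt
        fh.attrs["units"] = signal.units
        fh.attrs["label"] = signal.label
        if signal.channel_z is not None:
            fh.attrs["channel_z"] = signal.channel_z


def read_signals(path):
    import h5py

    from .signal_engine import SignalSet

    with h5py.File(path, "r") as fh:
        return SignalSet(
            traces=fh["traces"][()], dt=float(fh.attrs["dt"]),
            label=str(fh.attrs["label"]), units=str(fh.attrs["units"]),
            channel_z=(np.asarray(fh.attrs["channel_z"])
                       if "channel_z" in fh.attrs else None))
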