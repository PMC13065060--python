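"""Train the spectral-preserving model on a small synthetic dataset.

A compressed version of the full experiment (fewer epochs than the
desk-scale study, one seed) that still exercises the whole pipeline:
simulate -> scan-level split -> seeded training with augmentation and the
plateau/early-stopping protocol -> external-test evaluation with the full
metric suite.  Takes a few minutes on one CPU core.
"""

from spectraseg.dataio import simulate_dataset
from spectraseg.experiments import desk_scale_network, desk_scale_protocol
from spectraseg.phantom import AcquisitionParams
from spectraseg.training import evaluate_external, make_split, train_model

acq = AcquisitionParams(image_size=96, n_slices=100, seed=0)
manifest = simulate_dataset(5, acq, "example_output/train_data")
split = make_split([s["scan_id"] for s in manifest["scans"]], seed=0)
print(f"split: train={split.train_scans} val={split.val_scans} "
      f"test={split.test_scans}")

protocol = desk_scale_protocol(max_epochs=14)
config = desk_scale_network("spff")
ckpt, history, net = train_model(config, protocol, split,
                                 "example_output/train_data", seed=0,
                                 out_dir="example_output/run", verbose=True)
print(f"stopped: {history.stop_reason} after {len(history.train_loss)} "
      f"epochs; best epoch {history.best_epoch}")

result = evaluate_external(None, "example_output/train_data",
                           out_dir="example_output/eval", net=net,
                           split=split, tile=protocol.crop_size)
macro = result["macro"]["macro"]
print("external-test macro metrics "
      "(unweighted mean over foreground classes present):")
for name, value in macro.items():
    print(f"  {name:>12}: {value:.3f}")
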