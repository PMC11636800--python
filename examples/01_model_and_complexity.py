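"""Build the full-size network and account for its size and compute cost.

Constructs the default configuration (four-stage transformer branch with
efficient self-attention, ResNet-50 residual branch, convolutional fusion,
U-Net decoder, two heads), counts trainable parameters, and estimates
forward-pass FLOPs at 512x512 under the multiply-accumulate convention.
"""

from resmtunet import ModelConfig, ResMTUNet, count_parameters, estimate_flops

cfg = ModelConfig()
params = count_parameters(cfg)
gflops = estimate_flops(cfg, input_size=512) / 1e9
print(f"trainable parameters : {params:,}  ({params / 1e6:.2f}M)")
print(f"forward GFLOPs @512px: {gflops:.2f}")

model = ResMTUNet(cfg)
constructed = model.num_parameters()
print(f"constructed model agrees: {constructed == params}")

# The parameter count measures model capacity; the FLOP estimate is the
# arithmetic cost of segmenting one 512x512 tile.
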