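"""Build the standard segmentation network plan and print its layer table.

The plan is purely declarative: 16 3x3 convolutions in four encoder and four
mirrored decoder blocks, six 1x1 projection skip paths and four identity
skip paths.  The printed table lists, per layer, the activation shape and
the trainable parameter counts (convolution + batch norm); for the
reference 447x447x3 input the deepest feature map is 27x27x512 and the
output is a 447x447x2 class map.
"""

from vessnet import TensorShape, describe_plan, plan_vessnet

plan = plan_vessnet(TensorShape(447, 447, 3), num_classes=2)
print(describe_plan(plan))
print()
print(f"3x3 conv layers : {len(plan.conv_layers())}")
print(f"residual links  : {len(plan.links)} "
      f"({sum(l.kind == 'projection' for l in plan.links)} projection, "
      f"{sum(l.kind == 'identity' for l in plan.links)} identity)")
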