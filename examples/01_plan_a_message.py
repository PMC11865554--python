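"""Plan messages for one goal configuration under the three model variants.

The Sender starts at (1,1), her own goal is (1,3), and the Receiver's hidden
goal is (0,2) — an indirect trial: the Receiver's goal is off the straight
two-step path.  The full model detours through the Receiver's goal and marks
steps with Shannon surprise; the state variant walks straight home and never
communicates; the movement variant zigzags.
"""

import numpy as np

from tacit import GoalConfiguration, generate_message
from tacit.behavior import classify_message
from tacit.synthetic import DEFAULT_GROUP_PARAMS

config = GoalConfiguration(start=(1, 1), sender_goal=(1, 3), receiver_goal=(0, 2))

for variant in ("surprise", "state", "movement"):
    plan = generate_message(config, variant, DEFAULT_GROUP_PARAMS[variant],
                            rng=np.random.default_rng(0))
    msg = plan.message
    print(f"{variant:9s} {classify_message(msg):10s} "
          f"visits rg: {str(msg.visits(config.receiver_goal)):5s} "
          f"points: {plan.total_points:4.0f}")
    print(f"          path: {' -> '.join(map(str, msg.states))}")
    print(f"          surprise (bits/step): "
          f"{np.round(msg.step_surprise, 2).tolist()}")

# The per-step surprise is what the Receiver is assumed to decode: the step
# with the largest value is the Sender's candidate for "look here".
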