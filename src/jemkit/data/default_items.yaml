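# Default ten-item demand/control set (QPSNordic-guided short form).
#
# Four psychological-demand items and six decision-latitude (job control)
# items, all on 1-5 frequency scales. `adverse_high` states the orientation
# of each raw scale: true means larger raw values indicate more adverse
# exposure. The source surveys do not publish per-item codings, so the
# control-item orientations below are documented assumptions: frequent
# opportunity to decide/use/develop is protective (adverse_high: false,
# responses are reflected before analysis), frequent monotony is adverse.
name: default
items:
  - item_id: quantitative_demands
    label: Quantitative demands (too much to do)
    dimension: demand
    scale_min: 1
    scale_max: 5
    adverse_high: true
  - item_id: conflicting_ways
    label: Conflicting ways of doing things
    dimension: demand
    scale_min: 1
    scale_max: 5
    adverse_high: true
  - item_id: insufficient_resources
    label: Insufficient resources to complete tasks
    dimension: demand
    scale_min: 1
    scale_max: 5
    adverse_high: true
  - item_id: contradictory_requests
    label: Contradictory requests
    dimension: demand
    scale_min: 1
    scale_max: 5
    adverse_high: true
  - item_id: decide_how
    label: Decide how to go about the work
    dimension: control
    scale_min: 1
    scale_max: 5
    adverse_high: false
  - item_id: decide_pace
    label: Decide the pace of work
    dimension: control
    scale_min: 1
    scale_max: 5
    adverse_high: false
  - item_id: important_decisions
    label: Take part in important decisions
    dimension: control
    scale_min: 1
    scale_max: 5
    adverse_high: false
  - item_id: use_skills
    label: Use skills and knowledge
    dimension: control
    scale_min: 1
    scale_max: 5
    adverse_high: false
  - item_id: develop_skills
    label: Opportunity to develop skills
    dimension: control
    scale_min: 1
    scale_max: 5
    adverse_high: false
  - item_id: monotonous_work
    label: Monotonous, repetitive work
    dimension: control
    scale_min: 1
    scale_max: 5
    adverse_high: true
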