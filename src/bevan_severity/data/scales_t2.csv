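scale_value,damage_type
0,Predator insects of bark insects; feed on decay fungi on wood
1,Insects not directly damaging wood material but breeding between bark and wood; cause minor economic losses
2,Insects damaging wood surface only and insects harming decaying wood and their predators
3,Insects causing heavy damage to wood
4,Insects generating excessive damage to wood material; lower technical specifications and cause major economic losses
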