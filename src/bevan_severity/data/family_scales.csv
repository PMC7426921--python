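family,scale_value,damage_type
Cerambycidae,4,Wood-boring larvae generating excessive damage; lower technical specifications and cause major economic losses
Buprestidae,4,Larvae heavily attack bark cambium and wood; major economic losses
Anobiidae,4,Turn construction wood sponge-like; excessive damage to wood material
Melandryidae,4,Damage logs and lumber lowering technical specifications
Curculionidae/Scolytinae,1,Breed between bark and wood; minor economic losses
Curculionidae,1,Breed between bark and wood; minor economic losses
Tenebrionidae,2,Larvae in long-term stored and partially decayed wood; tunnel in stored wood
Elateridae,2,Larvae in long-term stored and partially decayed wood; partly predatory
Lucanidae,2,Larvae in long-term stored and partially decayed wood
Scarabaeidae,2,Larvae in long-term stored and partially decayed wood
Cossidae,3,Wood-moth larvae causing heavy damage to wood
Siricidae,3,Wood-wasp larvae causing heavy damage to wood
Rhinotermitidae,3,Subterranean termites causing heavy damage to wood
Formicidae,3,Carpenter ants tunnelling stored wood; heavy damage
Anobiidae/Ptinidae,4,Turn construction wood sponge-like; excessive damage to wood material
Silvanidae,1,Live under bark; minor economic losses
Oedemeridae,2,Larvae in damp decaying wood; surface damage only
Lycidae,2,Larvae in decaying wood
Cantharidae,0,Predator insects of bark insects
Cleridae,0,Predator insects of bark insects
Trogositidae,0,Predator insects of bark insects
Zopheridae,0,Predators and fungus feeders on wood
Dasytidae,0,Predator insects of bark insects
Mordellidae,0,Feed on decay fungi on wood
Cerylonidae,0,Feed on decay fungi on wood
Nitidulidae,0,Feed on decay fungi and tree sap
Pentatomidae,0,Sap-feeding bug; no wood damage
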