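phage_id,genus,family,genome_size_bp,lifestyle_score,lifestyle_verdict,receptor_class,dispersal,killing,receptor_unknown_reason,host_range_percent
EPa2,Bruynoghevirus,unclassified,43299,,lytic,1,+,+,,32.7
EPa4,Bruynoghevirus,unclassified,45439,0.9995,lytic,1,+,+,,31.4
EPa5,Epaquintavirus,Mesyanzhinovviridae,64096,,lytic,2,-,+,,18.6
EPa6,Pbunavirus,Lindbergviridae,66031,,lytic,2,-,+,,46.2
EPa7,Pbunavirus,Lindbergviridae,65629,,lytic,2,-,+,,44.2
EPa10,Pbunavirus,Lindbergviridae,66774,,lytic,3,-,+,,40.4
EPa11,Pbunavirus,Lindbergviridae,66800,,lytic,3,-,+,,51.3
EPa12,Pbunavirus,Lindbergviridae,66520,,lytic,3,-,+,,46.2
EPa13,Pbunavirus,Lindbergviridae,65680,,lytic,4,-,+,,42.3
EPa14,Pbunavirus,Lindbergviridae,65797,,lytic,4,-,+,,42.3
EPa15,Pbunavirus,Lindbergviridae,66002,,lytic,3,-,+,,54.5
EPa16,Nankokuvirus,Vandenendeviridae,88727,,lytic,unknown,-,+,PAO1-nonpermissive,35.9
EPa17,Nankokuvirus,Vandenendeviridae,88859,,lytic,unknown,-,+,PAO1-nonpermissive,30.8
EPa18,Nankokuvirus,Vandenendeviridae,88109,,lytic,unknown,-,+,PAO1-nonpermissive,37.8
EPa20,Pbunavirus,Lindbergviridae,66505,,lytic,3,-,+,,42.3
EPa21,Pbunavirus,Lindbergviridae,66764,,lytic,3,-,+,,39.7
EPa22,Pbunavirus,Lindbergviridae,65897,,lytic,4,-,+,,51.9
EPa24,Nankokuvirus,Vandenendeviridae,88728,,lytic,2,-,+,,46.8
EPa25,Pbunavirus,Lindbergviridae,66811,,lytic,3,-,+,,28.2
EPa26,Nankokuvirus,Vandenendeviridae,88805,,lytic,2,-,+,,42.9
EPa33,Hollowayvirus,unclassified,64021,0.075,temperate,5,-,+,,30.1
EPa38,Yuavirus,Mesyanzhinovviridae,61775,,lytic,2,-,+,,7.7
EPa39,Pbunavirus,Lindbergviridae,66708,,lytic,3,-,+,,45.5
EPa40,Septimatrevirus,unclassified,42788,,lytic,1,-,+,,32.7
EPa43,Epaquintavirus,Mesyanzhinovviridae,64323,0.75,lytic,2,-,+,,16.7
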