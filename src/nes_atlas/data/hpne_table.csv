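name,province,n_nes_total,n_nes1,n_nes2,n_nes3,lon_dms,lat_dms,protected,mining,substrate
Mont Panié 1,N,22,7,7,8,164°46′55″,20°33′54″,1,0,V
Mont Kouakoué,S,22,1,13,8,166°31′57″,21°57′35″,1,0,U
Mont Panié 2,N,21,9,3,9,164°45′45″,20°34′59″,1,0,V
Mont Mandjelia,N,20,4,10,6,164°32′03″,20°24′02″,0,0,V
Mont Humboldt,S,20,3,12,5,166°24′58″,21°53′16″,1,0,U
Roche Ouaième 1,N,17,8,5,4,164°51′29″,20°38′17″,0,0,V
Aoupinié 1,N,14,5,5,4,165°17′49″,21°10′56″,1,0,V
Mont Colnett,N,12,4,5,3,164°42′21″,20°30′37″,0,0,V
Roche Ouaième 2,N,12,5,5,2,164°52′38″,20°38′17″,0,0,V
Tontouta valley,S,12,5,4,3,166°15′41″,21°57′38″,0,1,U
Tiébaghi dome,N,11,4,3,4,164°11′19″,20°28′10″,0,1,U
Tchamba valley,N,11,1,4,6,165°14′24″,21°01′10″,0,0,V/U
Monts Koghis,S,11,7,3,1,166°30′50″,22°10′36″,1,0,U/V
Montagne des Sources,S,11,2,5,4,166°36′38″,22°06′15″,1,0,U
Mont Koniambo 1,N,10,4,1,5,164°44′23″,21°00′59″,0,1,U
Mont Boulinda 1,N,10,3,6,1,165°06′13″,21°18′28″,0,1,U
Ile Art (Belep),N,10,9,1,0,163°39′51″,19°41′10″,0,0,U
Avangui,N,10,2,5,3,165°05′03″,21°19′33″,0,1,U
Yaté South plateau,S,10,2,4,4,166°54′06″,22°09′25″,1,0,U
Mont Kaala,N,9,4,2,3,164°23′52″,20°36′58″,0,1,U
Mont Ignambi 1,N,9,1,3,5,164°35′28″,20°27′19″,0,0,V
Kathépahié,N,9,4,5,0,164°42′08″,20°55′33″,0,1,U
Aoupinié 2,N,9,1,3,5,165°18′59″,21°09′52″,1,0,V
Mine St Louis,N,9,2,3,4,165°06′12″,21°19′33″,0,1,U
Mont Boulinda 2,N,9,3,5,1,165°08′32″,21°16′19″,0,1,U
Mont Koniambo 2,N,9,5,1,3,164°46′42″,20°59′55″,0,1,U
Dogny,S,9,4,4,1,165°52′28″,21°37′03″,0,0,V
Montagne des Sources 2,S,9,2,1,6,166°36′38″,22°07′20″,1,0,U
Mont Paéoua,N,8,4,3,1,165°05′06″,21°10′53″,0,1,U
Aoupinié 3,N,8,4,3,1,165°18′59″,21°08′47″,1,0,V
Aoupinié 4,N,8,2,4,2,165°16′40″,21°10′56″,1,0,V
Mont Panié 3,N,8,4,1,3,164°46′55″,20°34′59″,1,0,V
Dumbea valley,S,8,2,5,1,166°28′30″,22°08′26″,0,0,U
Tontouta valley 2,S,8,5,2,1,166°20′20″,21°55′27″,0,1,U
Mont Mandjélia 2,N,8,1,5,2,164°30′55″,20°22′56″,0,0,V
Mont Ignambi 2,N,8,0,3,4,164°36′37″,20°27′20″,0,0,V
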