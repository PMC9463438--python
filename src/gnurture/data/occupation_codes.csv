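occ_code,label,class5,prestige11
1,professional_practice,professional_managerial,11
2,professional_education_health,professional_managerial,10
3,manager_administrator,professional_managerial,9
4,technical_worker,sales_service_admin,8
5,office_administrative,sales_service_admin,7
6,sales_worker,sales_service_admin,6
7,personal_service,sales_service_admin,4
8,craftsperson,manual_blue_collar,5
9,construction_worker,manual_blue_collar,4
10,transportation_worker,manual_blue_collar,4
11,factory_worker,manual_blue_collar,3
12,machine_operator,manual_blue_collar,3
13,farm_fishery_worker,manual_blue_collar,2
14,military_security,none_other,5
15,homemaker,none_other,1
16,other_occupation,none_other,1
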